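"""Per-layer characterization of the kinase hierarchy.

Once kinases are layered, each layer is profiled against the union of the
other kinase layers (one-versus-rest): impact breadth in the full
all-target network, impact on gene expression, essentiality fractions,
phosphorylation-site metrics, and so on. Phosphatases — which form no
hierarchy of their own — can be profiled as a fifth group against chosen
kinase layers. The outgroup is excluded from one-vs-rest tests by
default, matching the convention of dropping enzymes with no kinase-kinase
relationship from further analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import BOT, LAYERS, MID, OUTGROUP, TOP, ImpactNetwork, LayerAssignment
from .stats import ComparisonResult, fisher_2x2, rank_sum_test

__all__ = [
    "LayerProfile",
    "impact_breadth",
    "impact_breadth_table",
    "profile_numeric_by_layer",
    "profile_fraction_by_layer",
    "phosphatase_group_profile",
]


@dataclass(frozen=True)
class LayerProfile:
    """One layer (or group) against the rest, for one metric.

    ``per_group`` maps each group label to its median (numeric metrics)
    or flagged fraction (flag metrics), computed on measured values only.
    """

    focal: str
    metric: str
    per_group: Mapping[str, float]
    result: ComparisonResult


def impact_breadth(full_net: ImpactNetwork, enzyme: str) -> int:
    """Number of distinct proteins the enzyme impacts (out-degree in the
    full all-target network)."""
    if enzyme not in full_net:
        raise ValueError(f"enzyme {enzyme!r} not in network")
    return full_net.out_degree(enzyme)


def impact_breadth_table(full_net: ImpactNetwork, enzymes: Sequence[str]) -> dict:
    return {e: impact_breadth(full_net, e) for e in enzymes}


def _split(
    layers: LayerAssignment,
    values: Mapping[str, float],
    focal_layer: str,
    include_outgroup: bool,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    if focal_layer not in LAYERS:
        raise ValueError(f"unknown layer {focal_layer!r}")
    rest_layers = [
        l for l in (TOP, MID, BOT, OUTGROUP)
        if l != focal_layer and (include_outgroup or l != OUTGROUP)
    ]
    per_layer: dict[str, np.ndarray] = {}
    for layer in (TOP, MID, BOT, OUTGROUP):
        vals = np.array(
            [values[n] for n in layers.members(layer) if n in values], dtype=float
        )
        per_layer[layer] = vals[~np.isnan(vals)]
    focal = per_layer[focal_layer]
    rest = (
        np.concatenate([per_layer[l] for l in rest_layers])
        if rest_layers else np.array([])
    )
    if focal.size == 0:
        raise ValueError(f"no measured values in focal layer {focal_layer}")
    if rest.size == 0:
        raise ValueError("no measured values in the rest group")
    return focal, rest, per_layer


def profile_numeric_by_layer(
    layers: LayerAssignment,
    values: Mapping[str, float],
    focal_layer: str,
    tail: str = "two-sided",
    metric: str = "",
    include_outgroup: bool = False,
    method: str = "auto",
) -> LayerProfile:
    """Rank-sum test of one layer's numeric values against the other layers.

    ``values`` maps enzyme id to a measured number (e.g. the count of
    genes differentially expressed on inactivating that enzyme); ids
    absent from the mapping or NaN count as unmeasured.
    """
    focal, rest, per_layer = _split(layers, values, focal_layer, include_outgroup)
    result = rank_sum_test(
        focal, rest, tail=tail, method=method, metric=metric,
        labels=(focal_layer, "rest"),
    )
    per_group = {
        l: (float(np.median(v)) if v.size else float("nan"))
        for l, v in per_layer.items()
    }
    return LayerProfile(focal_layer, metric, per_group, result)


def profile_fraction_by_layer(
    layers: LayerAssignment,
    flags: Mapping[str, float],
    focal_layer: str,
    tail: str = "two-sided",
    metric: str = "",
    include_outgroup: bool = False,
) -> LayerProfile:
    """Fisher test of one layer's flagged fraction against the other layers."""
    focal, rest, per_layer = _split(layers, flags, focal_layer, include_outgroup)
    result = fisher_2x2(
        int((focal > 0).sum()), int((focal <= 0).sum()),
        int((rest > 0).sum()), int((rest <= 0).sum()),
        tail=tail, metric=metric, labels=(focal_layer, "rest"),
    )
    per_group = {
        l: (float((v > 0).mean()) if v.size else float("nan"))
        for l, v in per_layer.items()
    }
    return LayerProfile(focal_layer, metric, per_group, result)


def phosphatase_group_profile(
    phosphatase_ids: Sequence[str],
    layers: LayerAssignment,
    values: Mapping[str, float],
    metric: str = "",
    kind: str = "numeric",
    against: Sequence[str] = (MID, BOT),
    tail: str = "two-sided",
    method: str = "auto",
) -> LayerProfile:
    """Profile phosphatases as a fifth group against chosen kinase layers.

    ``against`` selects which kinase layers form the comparison group
    (default middle + bottom, the layers phosphatase impacts mostly
    reach).
    """
    if not phosphatase_ids:
        raise ValueError("empty phosphatase set")
    pho = np.array(
        [values[p] for p in phosphatase_ids if p in values], dtype=float
    )
    pho = pho[~np.isnan(pho)]
    if pho.size == 0:
        raise ValueError("no measured phosphatase values")
    kin_vals = []
    for layer in against:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        kin_vals.extend(
            values[n] for n in layers.members(layer) if n in values
        )
    kin = np.asarray(kin_vals, dtype=float)
    kin = kin[~np.isnan(kin)]
    if kin.size == 0:
        raise ValueError("no measured kinase values in comparison layers")

    if kind == "numeric":
        result = rank_sum_test(
            pho, kin, tail=tail, method=method, metric=metric,
            labels=("phosphatase", "+".join(against)),
        )
        per_group = {"phosphatase": float(np.median(pho)),
                     "+".join(against): float(np.median(kin))}
    elif kind == "flag":
        result = fisher_2x2(
            int((pho > 0).sum()), int((pho <= 0).sum()),
            int((kin > 0).sum()), int((kin <= 0).sum()),
            tail=tail, metric=metric,
            labels=("phosphatase", "+".join(against)),
        )
        per_group = {"phosphatase": float((pho > 0).mean()),
                     "+".join(against): float((kin > 0).mean())}
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return LayerProfile("phosphatase", metric, per_group, result)
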