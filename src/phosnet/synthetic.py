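"""Synthetic enzyme tables and planted-hierarchy impact networks.

Real inputs to the pipeline are (a) annotation tables for writer/eraser
enzyme classes (abundance, essentiality, PPI degree, responsiveness,
half-life, phosphorylation capacity, negative genetic interactions) and
(b) directed impact edge lists from phospho-proteomic screens. Neither is
bundled here; instead this module generates tables and networks with the
same statistical structure, so every downstream stage — layering, the
asymmetry battery, per-layer profiling — can be exercised and validated
end to end.

The default class parameters encode the budding-yeast conditions the
asymmetry analyses describe: 137 kinases vs 50 phosphatases, phosphatase
median abundance roughly double the kinase median (63 vs 30.4 ppm),
kinase essentiality 23% vs 10%, shorter kinase half-lives (33 vs 42 min
medians), higher kinase PPI connectivity, and a much higher kinase
capacity to be phosphorylated. Abundance dispersion defaults to the value
at which a rank-sum comparison of 137 vs 50 log-normal draws with those
medians is significant at roughly the reported level (p ~ 0.008).

Planted networks carry ground-truth layer labels constructed so that the
simple layering scheme is their exact inverse in the noiseless case:
planted TOP nodes receive no edges, planted BOT nodes emit none, planted
OUT nodes stay isolated, and planted MID nodes have both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import (
    BOT,
    MID,
    OUTGROUP,
    TOP,
    ImpactNetwork,
    LayerAssignment,
    build_network,
)

__all__ = [
    "ClassSpec",
    "EnzymeTableSpec",
    "PlantedNetworkSpec",
    "generate_enzyme_table",
    "generate_planted_network",
    "perturb_network",
    "yeast_table_spec",
    "YEAST_KINASE",
    "YEAST_PHOSPHATASE",
    "YEAST_BACKGROUND",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Raised when a network spec cannot be realized."""


# fixed substream codes: one independent random stream per (class, metric),
# so adding a metric never shifts the draws of existing ones
_STREAMS = {
    "abundance": 1,
    "essential": 2,
    "ppi_degree": 3,
    "de_responsive": 4,
    "de_perturbation_count": 5,
    "half_life": 6,
    "phospho_curated": 7,
    "phospho_peptide": 8,
    "phospho_conserved": 9,
    "conserved_sites": 10,
    "ngi_count": 11,
    "subclass": 12,
    "missing": 13,
}
_NETWORK_STREAM = 100
_SPURIOUS_STREAM = 101

#: numeric columns eligible for missing-at-random masking
MASKABLE = ("abundance", "ppi_degree", "half_life")


@dataclass(frozen=True)
class ClassSpec:
    """Distributional parameters for one enzyme class.

    Abundance and half-life are log-normal, parameterized by their median
    (ppm and minutes) and log-scale dispersion; PPI degree and NGI counts
    are negative binomial (mean plus a dispersion/size parameter, the
    usual overdispersed model for interaction counts); flags are
    Bernoulli; responsiveness is zero-inflated (a fraction responsive at
    all, and a geometric count of perturbations among responders).
    """

    name: str
    n_genes: int
    abundance_median: float = 30.0
    abundance_sigma: float = 1.75
    essential_rate: float = 0.2
    ppi_mean: float = 10.0
    ppi_dispersion: float = 0.7
    responsive_rate: float = 0.35
    responsive_count_mean: float = 4.0
    half_life_median: float = 40.0
    half_life_sigma: float = 0.6
    phospho_curated_rate: float = 0.3
    phospho_peptide_rate: float = 0.3
    phospho_conserved_rate: float = 0.25
    conserved_sites_mean: float = 2.0
    ngi_rate: float = 0.6
    ngi_count_mean: float = 3.0
    ngi_dispersion: float = 1.0
    tyrosine_rate: float = 0.1
    organism: str = "yeast"

    def validate(self) -> None:
        if not self.name:
            raise ValueError("field 'name' must be nonempty")
        if self.n_genes < 1:
            raise ValueError(f"field 'n_genes' must be >= 1, got {self.n_genes}")
        for f in ("abundance_median", "abundance_sigma", "ppi_mean",
                  "ppi_dispersion", "responsive_count_mean", "half_life_median",
                  "half_life_sigma", "conserved_sites_mean", "ngi_count_mean",
                  "ngi_dispersion"):
            v = getattr(self, f)
            if not v > 0:
                raise ValueError(f"field {f!r} must be > 0, got {v}")
        for f in ("essential_rate", "responsive_rate", "phospho_curated_rate",
                  "phospho_peptide_rate", "phospho_conserved_rate", "ngi_rate",
                  "tyrosine_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"field {f!r} must be in [0, 1], got {v}")


# Budding-yeast defaults. Gene counts, abundance medians, essentiality
# rates, half-life medians, responsive fractions and phospho-capacity
# contrasts follow the published yeast comparisons; dispersions and the
# remaining location parameters are chosen so the standard asymmetry
# battery at these sample sizes lands near the reported significance
# levels (see docs/methods.md).
YEAST_KINASE = ClassSpec(
    name="kinase", n_genes=137,
    abundance_median=30.4, abundance_sigma=1.75,
    essential_rate=0.23,
    ppi_mean=20.0, ppi_dispersion=0.7,
    responsive_rate=0.33, responsive_count_mean=5.0,
    half_life_median=33.0, half_life_sigma=0.6,
    phospho_curated_rate=0.45, phospho_peptide_rate=0.42,
    phospho_conserved_rate=0.40, conserved_sites_mean=3.0,
    ngi_rate=0.67, ngi_count_mean=2.2, ngi_dispersion=1.0,
    tyrosine_rate=0.05,
)
YEAST_PHOSPHATASE = ClassSpec(
    name="phosphatase", n_genes=50,
    abundance_median=63.0, abundance_sigma=1.75,
    essential_rate=0.10,
    ppi_mean=12.0, ppi_dispersion=0.7,
    responsive_rate=0.30, responsive_count_mean=2.5,
    half_life_median=42.0, half_life_sigma=0.6,
    phospho_curated_rate=0.10, phospho_peptide_rate=0.12,
    phospho_conserved_rate=0.08, conserved_sites_mean=1.5,
    ngi_rate=0.74, ngi_count_mean=5.0, ngi_dispersion=1.0,
    tyrosine_rate=0.08,
)
YEAST_BACKGROUND = ClassSpec(
    name="protein", n_genes=4925,
    abundance_median=45.0, abundance_sigma=1.75,
    essential_rate=0.189,
    ppi_mean=8.0, ppi_dispersion=0.7,
    responsive_rate=0.44, responsive_count_mean=5.0,
    half_life_median=44.0, half_life_sigma=0.6,
    phospho_curated_rate=0.25, phospho_peptide_rate=0.25,
    phospho_conserved_rate=0.20, conserved_sites_mean=2.0,
    ngi_rate=0.5, ngi_count_mean=2.5, ngi_dispersion=1.0,
    tyrosine_rate=0.0,
)


@dataclass(frozen=True)
class EnzymeTableSpec:
    """A set of class specs plus the global seed and missingness rates."""

    classes: tuple[ClassSpec, ...]
    seed: int
    missing_rates: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.classes:
            raise ValueError("field 'classes' must be nonempty")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate class names: {names}")
        for c in self.classes:
            c.validate()
        for metric, rate in self.missing_rates.items():
            if metric not in MASKABLE:
                raise ValueError(
                    f"field 'missing_rates': unknown metric {metric!r} "
                    f"(maskable: {MASKABLE})"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValueError(
                    f"field 'missing_rates[{metric}]' must be in [0, 1], got {rate}"
                )


def yeast_table_spec(seed: int, with_background: bool = True,
                     missing_rate: float = 0.015) -> EnzymeTableSpec:
    """The default budding-yeast study conditions."""
    classes = [YEAST_KINASE, YEAST_PHOSPHATASE]
    if with_background:
        classes.append(YEAST_BACKGROUND)
    return EnzymeTableSpec(
        classes=tuple(classes),
        seed=seed,
        missing_rates={m: missing_rate for m in MASKABLE},
    )


def _rng(seed: int, class_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), class_idx, stream])


def _negative_binomial(rng: np.random.Generator, mean: float,
                       dispersion: float, n: int) -> np.ndarray:
    # dispersion = NB size parameter k; variance = mean + mean^2 / k
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n).astype(float)


def generate_enzyme_table(spec: EnzymeTableSpec) -> pd.DataFrame:
    """Draw one annotation table.

    Returns a DataFrame with one row per gene and the columns
    ``id, organism, enzyme_class, subclass, abundance, essential,
    ppi_degree, de_responsive, de_perturbation_count, half_life,
    phospho_curated, phospho_peptide, phospho_conserved, conserved_sites,
    ngi_count``. Flags are encoded 1.0/0.0 and missing values as NaN.
    Output is deterministic in the spec (including the seed), and each
    (class, metric) pair draws from its own substream.
    """
    spec.validate()
    frames = []
    for ci, cls in enumerate(spec.classes):
        n = cls.n_genes
        width = max(3, len(str(n)))
        ids = [f"{cls.name[:3].upper()}{i:0{width}d}" for i in range(n)]

        abundance = _rng(spec.seed, ci, _STREAMS["abundance"]).lognormal(
            np.log(cls.abundance_median), cls.abundance_sigma, n
        )
        essential = (
            _rng(spec.seed, ci, _STREAMS["essential"]).random(n)
            < cls.essential_rate
        ).astype(float)
        ppi = _negative_binomial(
            _rng(spec.seed, ci, _STREAMS["ppi_degree"]), cls.ppi_mean,
            cls.ppi_dispersion, n,
        )
        responsive = (
            _rng(spec.seed, ci, _STREAMS["de_responsive"]).random(n)
            < cls.responsive_rate
        ).astype(float)
        # count of perturbations with differential expression: zero unless
        # responsive, then 1 + geometric so the support starts at 1
        geo_p = 1.0 / cls.responsive_count_mean
        counts = _rng(spec.seed, ci, _STREAMS["de_perturbation_count"]).geometric(
            geo_p, n
        ).astype(float)
        de_count = np.where(responsive > 0, counts, 0.0)
        half_life = _rng(spec.seed, ci, _STREAMS["half_life"]).lognormal(
            np.log(cls.half_life_median), cls.half_life_sigma, n
        )
        phospho = {}
        for col, rate in (
            ("phospho_curated", cls.phospho_curated_rate),
            ("phospho_peptide", cls.phospho_peptide_rate),
            ("phospho_conserved", cls.phospho_conserved_rate),
        ):
            phospho[col] = (
                _rng(spec.seed, ci, _STREAMS[col]).random(n) < rate
            ).astype(float)
        sites = _negative_binomial(
            _rng(spec.seed, ci, _STREAMS["conserved_sites"]),
            cls.conserved_sites_mean, 1.0, n,
        )
        conserved_sites = np.where(phospho["phospho_conserved"] > 0, 1 + sites, 0.0)
        ngi_rng = _rng(spec.seed, ci, _STREAMS["ngi_count"])
        has_ngi = ngi_rng.random(n) < cls.ngi_rate
        ngi_extra = _negative_binomial(
            ngi_rng, cls.ngi_count_mean, cls.ngi_dispersion, n
        )
        ngi = np.where(has_ngi, 1 + ngi_extra, 0.0)
        subclass = np.where(
            _rng(spec.seed, ci, _STREAMS["subclass"]).random(n) < cls.tyrosine_rate,
            "tyrosine", "ser_thr",
        )

        frame = pd.DataFrame(
            {
                "id": ids,
                "organism": cls.organism,
                "enzyme_class": cls.name,
                "subclass": subclass,
                "abundance": abundance,
                "essential": essential,
                "ppi_degree": ppi,
                "de_responsive": responsive,
                "de_perturbation_count": de_count,
                "half_life": half_life,
                **phospho,
                "conserved_sites": conserved_sites,
                "ngi_count": ngi,
            }
        )
        mask_rng = _rng(spec.seed, ci, _STREAMS["missing"])
        for metric in MASKABLE:
            rate = spec.missing_rates.get(metric, 0.0)
            if rate > 0:
                frame.loc[mask_rng.random(n) < rate, metric] = np.nan
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """A planted three-layer hierarchy plus isolated outgroup nodes.

    Edges are drawn independently within four strata (top->mid, top->bot,
    mid->bot, mid->mid); each planted TOP/MID node is then topped up to
    ``min_out`` outgoing edges and each MID/BOT node to ``min_in``
    incoming edges, without ever giving TOP an incoming or BOT an
    outgoing edge. ``n_spurious`` uniform random extra edges (any
    non-duplicate, non-self pair) are added afterwards from a separate
    random substream, so the noise-free part of the network is unchanged.
    """

    n_top: int
    n_mid: int
    n_bot: int
    n_out: int = 0
    p_top_mid: float = 0.4
    p_top_bot: float = 0.2
    p_mid_bot: float = 0.4
    p_mid_mid: float = 0.1
    min_out: int = 1
    min_in: int = 1
    n_spurious: int = 0
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_top", "n_mid", "n_bot", "n_out", "n_spurious"):
            if getattr(self, f) < 0:
                raise ValueError(f"field {f!r} must be >= 0")
        for f in ("p_top_mid", "p_top_bot", "p_mid_bot", "p_mid_mid"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"field {f!r} must be in [0, 1], got {v}")
        if self.min_out < 1 or self.min_in < 1:
            raise ValueError("fields 'min_out'/'min_in' must be >= 1")
        # feasibility of the degree floors
        if self.n_top > 0 and self.n_mid + self.n_bot < self.min_out:
            raise GenerationError(
                "TOP nodes cannot reach min_out: too few MID+BOT targets"
            )
        if self.n_mid > 0 and self.n_bot + self.n_mid - 1 < self.min_out:
            raise GenerationError(
                "MID nodes cannot reach min_out: too few BOT+MID targets"
            )
        if self.n_mid > 0 and self.n_top + self.n_mid - 1 < self.min_in:
            raise GenerationError(
                "MID nodes cannot reach min_in: too few TOP+MID sources"
            )
        if self.n_bot > 0 and self.n_top + self.n_mid < self.min_in:
            raise GenerationError(
                "BOT nodes cannot reach min_in: too few TOP+MID sources"
            )


def _top_up(rng: np.random.Generator, edges: set, node: str,
            candidates: Sequence[str], need: int, incoming: bool) -> None:
    pool = [c for c in candidates if c != node]
    rng.shuffle(pool)
    for cand in pool:
        if need <= 0:
            return
        e = (cand, node) if incoming else (node, cand)
        if e not in edges:
            edges.add(e)
            need -= 1
    if need > 0:
        raise GenerationError(
            f"cannot satisfy degree floor for node {node}: candidate pool exhausted"
        )


def generate_planted_network(
    spec: PlantedNetworkSpec,
) -> tuple[ImpactNetwork, LayerAssignment]:
    """Draw one planted network and its ground-truth layer labels.

    With ``n_spurious=0`` the simple layering scheme recovers the planted
    labels exactly (TOP never targeted, BOT never impacting, OUT
    isolated, MID both).
    """
    spec.validate()
    top = [f"T{i:03d}" for i in range(spec.n_top)]
    mid = [f"M{i:03d}" for i in range(spec.n_mid)]
    bot = [f"B{i:03d}" for i in range(spec.n_bot)]
    out = [f"O{i:03d}" for i in range(spec.n_out)]

    rng = np.random.default_rng([int(spec.seed), _NETWORK_STREAM])
    edges: set[tuple[str, str]] = set()
    for stratum, sources, targets in (
        (spec.p_top_mid, top, mid),
        (spec.p_top_bot, top, bot),
        (spec.p_mid_bot, mid, bot),
        (spec.p_mid_mid, mid, mid),
    ):
        for u in sources:
            for v in targets:
                if u != v and rng.random() < stratum:
                    edges.add((u, v))

    def out_deg(n): return sum(1 for u, _ in edges if u == n)
    def in_deg(n): return sum(1 for _, v in edges if v == n)

    for t in top:
        _top_up(rng, edges, t, mid + bot, spec.min_out - out_deg(t), incoming=False)
    for m in mid:
        _top_up(rng, edges, m, mid + bot, spec.min_out - out_deg(m), incoming=False)
    for m in mid:
        _top_up(rng, edges, m, top + mid, spec.min_in - in_deg(m), incoming=True)
    for b in bot:
        _top_up(rng, edges, b, top + mid, spec.min_in - in_deg(b), incoming=True)

    net = build_network(sorted(edges), node_universe=top + mid + bot + out)
    truth = LayerAssignment(
        {**{n: TOP for n in top}, **{n: MID for n in mid},
         **{n: BOT for n in bot}, **{n: OUTGROUP for n in out}},
        scheme="planted",
    )
    if spec.n_spurious > 0:
        net = perturb_network(
            net, spec.n_spurious,
            seed=np.random.default_rng([int(spec.seed), _SPURIOUS_STREAM]),
        )
    return net, truth


def perturb_network(
    net: ImpactNetwork, n_spurious: int, seed
) -> ImpactNetwork:
    """Add ``n_spurious`` random non-duplicate, non-self edges.

    Original edges are preserved; added edges carry the provenance tag
    ``"spurious"``. ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_spurious < 0:
        raise ValueError(f"n_spurious must be >= 0, got {n_spurious}")
    result = net.copy()
    if n_spurious == 0:
        return result
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        [int(seed), _SPURIOUS_STREAM]
    )
    nodes = sorted(net.nodes)
    candidates = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and not net.graph.has_edge(u, v)
    ]
    if len(candidates) < n_spurious:
        raise GenerationError(
            f"graph too small: {len(candidates)} free node pairs, "
            f"{n_spurious} spurious edges requested"
        )
    chosen = rng.choice(len(candidates), size=n_spurious, replace=False)
    for idx in sorted(chosen):
        u, v = candidates[idx]
        result.graph.add_edge(u, v, provenance="spurious")
    return result
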