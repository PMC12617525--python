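"""Synthetic co-elution and spatial-expression data with planted ground truth.

The generator emulates the study design the pipeline targets: size-exclusion
chromatography of brain lysates from four genotypes (a wild-type reference
plus rewired mutants), measured over 96 fractions by several search engines,
where members of an intact protein complex co-elute as a shared Gaussian
abundance peak. Genotype rewiring deletes, splits, or apex-shifts planted
complexes, providing exact ground truth for every downstream stage. A second
generator produces spot x gene negative-binomial count tables with planted
differentially expressed genes for the spatial scoring arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import COMPARTMENTS, ComplexCatalog, ElutionMatrix

REFERENCE_GENOTYPE = "WT"

#: Rewiring actions a mutant genotype may apply to a baseline complex.
ACTIONS = ("kept", "deleted", "split", "apex_shifted")

#: Default per-genotype rewiring probabilities (remainder of mass -> kept),
#: emulating a design with a heterozygous and homozygous point mutant and a
#: knockout alongside the wild type.
DEFAULT_REWIRING: dict[str, dict[str, float]] = {
    "HET": {"deleted": 0.10, "split": 0.10, "apex_shifted": 0.10},
    "HOM": {"deleted": 0.20, "split": 0.15, "apex_shifted": 0.15},
    "KO": {"deleted": 0.30, "split": 0.20, "apex_shifted": 0.10},
}

_MITO_COMPARTMENTS = ("OMM", "IMS", "matrix", "inner_membrane")


@dataclass
class SimulationConfig:
    """Knobs of the co-elution simulator.

    Defaults encode the study conditions: 50 planted complexes of 3-8
    subunits across 96 SEC fractions, three search engines, moderate count
    noise and dropout.
    """

    n_complexes: int = 50
    complex_size_range: tuple[int, int] = (3, 8)
    n_background_proteins: int = 100
    n_fractions: int = 96
    peak_width_range: tuple[float, float] = (3.0, 6.0)
    apex_jitter: float = 0.25       # max |per-member apex offset|, fractions
    abundance_scale: float = 100.0  # peak height, arbitrary count units
    count_noise: float = 0.1        # NB overdispersion: var = mu + cn * mu^2
    dropout_prob: float = 0.2
    n_engines: int = 3
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.complex_size_range
        if lo < 3:
            raise ValueError("minimum complex size must be >= 3")
        if hi < lo:
            raise ValueError("complex_size_range must be (min, max) with min <= max")
        if self.n_fractions < 4:
            raise ValueError("n_fractions must be >= 4")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.n_complexes < 0 or self.n_background_proteins < 0:
            raise ValueError("counts must be non-negative")
        if self.count_noise < 0:
            raise ValueError("count_noise must be non-negative")
        if self.n_engines < 1:
            raise ValueError("need at least one engine")


@dataclass
class PlantedTruth:
    """Ground truth behind a simulated experiment.

    ``catalogs`` maps genotype -> complex catalog after rewiring;
    ``units`` maps genotype -> the co-eluting units actually simulated
    (split complexes appear as their parts). ``rewiring_log`` records the
    action applied to every baseline complex in every mutant genotype.
    """

    catalogs: dict[str, ComplexCatalog]
    units: dict[str, dict[str, frozenset[str]]]
    rewiring_log: list[tuple[str, str, str]]
    compartments: dict[str, str]
    background: frozenset[str]
    deg_truth: dict[str, float] = field(default_factory=dict)

    @property
    def genotypes(self) -> list[str]:
        return list(self.catalogs)

    def true_edges(self, genotype: str) -> set[tuple[str, str]]:
        """Unordered co-complex pairs present (co-eluting) in a genotype."""
        pairs: set[tuple[str, str]] = set()
        for members in self.units[genotype].values():
            srt = sorted(members)
            for i, a in enumerate(srt):
                for b in srt[i + 1:]:
                    pairs.add((a, b))
        return pairs

    def deleted_exclusive_pairs(self, genotype: str) -> set[tuple[str, str]]:
        """Pairs of complexes deleted in ``genotype`` that co-elute in the
        reference but in no unit of ``genotype``."""
        lost = self.true_edges(REFERENCE_GENOTYPE) - self.true_edges(genotype)
        deleted = {cid for g, cid, act in self.rewiring_log
                   if g == genotype and act == "deleted"}
        out: set[tuple[str, str]] = set()
        base = self.catalogs[REFERENCE_GENOTYPE]
        for cid in deleted:
            srt = sorted(base.complexes[cid])
            for i, a in enumerate(srt):
                for b in srt[i + 1:]:
                    if (a, b) in lost:
                        out.add((a, b))
        return out


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def generate_truth(config: SimulationConfig,
                   rewiring_spec: Mapping[str, Mapping[str, float]] | None = None,
                   ) -> PlantedTruth:
    """Plant a baseline complex catalog and rewire it per mutant genotype.

    ``rewiring_spec`` maps genotype -> {action: probability}; probabilities
    per genotype must sum to <= 1 (remaining mass keeps the complex intact).
    Deterministic given ``config.seed``.
    """
    config.validate()
    if rewiring_spec is None:
        rewiring_spec = DEFAULT_REWIRING
    for g, probs in rewiring_spec.items():
        bad = set(probs) - set(ACTIONS)
        if bad:
            raise ValueError(f"unknown rewiring action(s) {sorted(bad)} for {g!r}")
        if sum(probs.values()) > 1 + 1e-12:
            raise ValueError(f"rewiring probabilities for {g!r} sum above 1")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    n_members = int(sizes.sum())
    n_total = n_members + config.n_background_proteins
    width = max(4, len(str(max(n_total, 1))))
    proteins = [f"P{i:0{width}d}" for i in range(1, n_total + 1)]

    baseline: dict[str, frozenset[str]] = {}
    pos = 0
    for k, size in enumerate(sizes, start=1):
        baseline[f"CPX{k:03d}"] = frozenset(proteins[pos:pos + size])
        pos += int(size)
    background = frozenset(proteins[pos:])

    # Co-complex members share a compartment; background is labelled at random.
    compartments: dict[str, str] = {}
    for cid in sorted(baseline):
        label = _MITO_COMPARTMENTS[rng.integers(len(_MITO_COMPARTMENTS))]
        for p in baseline[cid]:
            compartments[p] = label
    for p in sorted(background):
        compartments[p] = COMPARTMENTS[rng.integers(len(COMPARTMENTS))]

    catalogs = {REFERENCE_GENOTYPE: ComplexCatalog(dict(baseline), source="planted")}
    units = {REFERENCE_GENOTYPE: dict(baseline)}
    rewiring_log: list[tuple[str, str, str]] = []

    for genotype in sorted(rewiring_spec):
        probs = rewiring_spec[genotype]
        order = [a for a in ACTIONS if a != "kept"]
        cut = np.cumsum([probs.get(a, 0.0) for a in order])
        cat: dict[str, frozenset[str]] = {}
        g_units: dict[str, frozenset[str]] = {}
        for cid in sorted(baseline):
            u = rng.random()
            action = "kept"
            for a, c in zip(order, cut):
                if u < c:
                    action = a
                    break
            rewiring_log.append((genotype, cid, action))
            members = baseline[cid]
            if action == "deleted":
                continue
            if action == "split":
                srt = sorted(members)
                perm = rng.permutation(len(srt))
                k = int(rng.integers(2, len(srt) - 1)) if len(srt) > 4 else 2
                part_a = frozenset(srt[i] for i in perm[:k])
                part_b = frozenset(srt[i] for i in perm[k:])
                cat[f"{cid}a"] = part_a
                cat[f"{cid}b"] = part_b
                g_units[f"{cid}a"] = part_a
                g_units[f"{cid}b"] = part_b
            else:  # kept or apex_shifted: membership intact
                cat[cid] = members
                g_units[cid] = members
        catalogs[genotype] = ComplexCatalog(cat, source="planted")
        units[genotype] = g_units

    return PlantedTruth(catalogs=catalogs, units=units,
                        rewiring_log=rewiring_log,
                        compartments=compartments, background=background)


def apply_rewiring_log(baseline: ComplexCatalog,
                       log: Sequence[tuple[str, str, str]],
                       genotype: str) -> set[frozenset[str]]:
    """Re-derive a genotype's catalog membership sets from the rewiring log.

    Used to audit that the log is a faithful record: actions applied to the
    baseline reproduce the stored catalog (split part compositions are not
    recorded in the log, so splits are compared as unions).
    """
    out: set[frozenset[str]] = set()
    for g, cid, action in log:
        if g != genotype:
            continue
        members = baseline.complexes[cid]
        if action in ("kept", "apex_shifted", "split"):
            out.add(members)
    return out


# ---------------------------------------------------------------------------
# Elution simulation
# ---------------------------------------------------------------------------

def _gaussian_profile(n_fractions: int, apex: np.ndarray, widths: np.ndarray,
                      amps: np.ndarray) -> np.ndarray:
    grid = np.arange(n_fractions, dtype=float)[None, :]
    return amps[:, None] * np.exp(
        -((grid - apex[:, None]) ** 2) / (2.0 * widths[:, None] ** 2))


def simulate_elution(truth: PlantedTruth, config: SimulationConfig,
                     genotype: str, extract: str = "Mt") -> list[ElutionMatrix]:
    """Draw one elution matrix per search engine for one genotype.

    Members of each surviving co-eluting unit share a Gaussian peak (common
    apex +- small per-member jitter); background proteins and members of
    deleted complexes get independent random apexes. With ``count_noise`` > 0,
    engines observe independent negative-binomial draws around the underlying
    profile; dropout then zeroes cells independently per (protein, fraction).
    """
    config.validate()
    if genotype not in truth.catalogs:
        raise ValueError(f"unknown genotype {genotype!r}; have {truth.genotypes}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash(genotype), 17]))

    proteins = sorted(set(truth.compartments))
    index = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)
    nf = config.n_fractions
    w_lo, w_hi = config.peak_width_range
    margin = min(2.0 * w_hi, nf / 4.0)

    apex = np.empty(n)
    widths = np.empty(n)
    assigned = np.zeros(n, dtype=bool)
    for uid in sorted(truth.units[genotype]):
        members = truth.units[genotype][uid]
        a = rng.uniform(margin, nf - 1 - margin)
        w = rng.uniform(w_lo, w_hi)
        for p in sorted(members):
            i = index[p]
            apex[i] = a + rng.uniform(-config.apex_jitter, config.apex_jitter)
            widths[i] = w
            assigned[i] = True
    # free proteins (background + members of complexes absent in this genotype)
    for i in np.flatnonzero(~assigned):
        apex[i] = rng.uniform(margin, nf - 1 - margin)
        widths[i] = rng.uniform(w_lo, w_hi)

    amps = config.abundance_scale * rng.lognormal(mean=0.0, sigma=0.35, size=n)
    profile = _gaussian_profile(nf, apex, widths, amps)

    matrices: list[ElutionMatrix] = []
    for e in range(1, config.n_engines + 1):
        if config.count_noise > 0:
            # NB with var = mu + cn * mu^2 via gamma-Poisson mixture
            shape = 1.0 / config.count_noise
            lam = profile * rng.gamma(shape, 1.0 / shape, size=profile.shape)
            values = rng.poisson(lam).astype(float)
        else:
            values = profile.copy()
        if config.dropout_prob > 0:
            keep = rng.random(values.shape) >= config.dropout_prob
            values = values * keep
        cols = [f"fraction_{j:03d}" for j in range(1, nf + 1)]
        df = pd.DataFrame(values, index=proteins, columns=cols)
        matrices.append(ElutionMatrix(df, genotype=genotype, extract=extract,
                                      engine=f"engine{e}"))
    return matrices


def _stable_hash(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 31)
    return h


# ---------------------------------------------------------------------------
# Planted scored networks (for clustering-stage tests)
# ---------------------------------------------------------------------------

def planted_network(truth: PlantedTruth, genotype: str,
                    within_score: float = 0.95,
                    background_score: float = 0.05,
                    extract: str = "Mt"):
    """Noise-free scored network: co-complex pairs at ``within_score``, all
    other protein pairs at ``background_score``."""
    from .io import ScoredNetwork
    proteins = sorted(truth.compartments)
    true = truth.true_edges(genotype)
    edges: dict[tuple[str, str], float] = {}
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            edges[(a, b)] = within_score if (a, b) in true else background_score
    return ScoredNetwork(edges, threshold=0.0, genotype=genotype, extract=extract)


# ---------------------------------------------------------------------------
# Spatial spot counts
# ---------------------------------------------------------------------------

#: Dopaminergic markers used for region spot selection in the spatial arm.
DEFAULT_MARKERS = ("Th", "Dat", "Vmat2")


@dataclass
class SpotExpression:
    """Spot x gene count table with per-spot region/group/soma annotations."""

    counts: pd.DataFrame                 # spots x genes, non-negative ints
    obs: pd.DataFrame                    # region, group, soma_flag per spot
    marker_genes: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = {"region", "group", "soma_flag"} - set(self.obs.columns)
        if missing:
            raise ValueError(f"obs missing columns {sorted(missing)}")
        if not self.counts.index.equals(self.obs.index):
            raise ValueError("counts and obs must share the spot index")


def simulate_spots(n_per_group: int = 20, n_genes: int = 2000,
                   deg_frac: float = 0.2, effect_size: float = 2.0,
                   seed: int = 0, region: str = "SN",
                   groups: tuple[str, str] = ("WT", "HOM"),
                   dispersion: float = 0.3,
                   soma_prob: float = 0.85) -> tuple[SpotExpression, dict[str, float]]:
    """Negative-binomial spot counts with planted DEGs.

    A ``deg_frac`` fraction of genes receives a +-``effect_size`` log2 mean
    shift in the second group (half up, half down). Marker genes are appended
    with high expression in ``region`` spots so marker-based selection is
    exercisable; a minority of spots belongs to an off-target region or lacks
    a complete neuron soma. Returns the table and the planted gene -> log2
    effect mapping.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if not (0 <= deg_frac <= 1):
        raise ValueError("deg_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    base_mu = rng.lognormal(mean=np.log(8.0), sigma=1.0, size=n_genes)

    n_deg = int(round(deg_frac * n_genes))
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    signs = np.where(np.arange(n_deg) % 2 == 0, 1.0, -1.0)
    deg_truth = {genes[i]: float(s * effect_size)
                 for i, s in zip(deg_idx, signs)}

    # extra spots that will fail region / soma criteria
    n_extra = max(2, n_per_group // 4)
    spot_rows = []
    for g in groups:
        for k in range(n_per_group):
            spot_rows.append((f"{g}_s{k:03d}", region, g, bool(rng.random() < soma_prob)))
    for k in range(n_extra):
        g = groups[k % 2]
        spot_rows.append((f"{g}_off{k:02d}", "thalamus", g, True))
    obs = pd.DataFrame(spot_rows, columns=["spot", "region", "group", "soma_flag"]
                       ).set_index("spot")

    mu = np.tile(base_mu, (len(obs), 1))
    fold = np.ones(n_genes)
    for i, s in zip(deg_idx, signs):
        fold[i] = 2.0 ** (s * effect_size)
    second = (obs["group"] == groups[1]).to_numpy()
    mu[second, :] *= fold[None, :]

    shape = 1.0 / dispersion
    lam = mu * rng.gamma(shape, 1.0 / shape, size=mu.shape)
    counts = rng.poisson(lam).astype(np.int64)

    # markers: strong in the target region, weak elsewhere
    marker_mu = np.where(obs["region"].to_numpy() == region, 60.0, 1.0)
    marker_counts = rng.poisson(
        np.tile(marker_mu[:, None], (1, len(DEFAULT_MARKERS)))).astype(np.int64)

    table = pd.DataFrame(np.hstack([counts, marker_counts]), index=obs.index,
                         columns=genes + list(DEFAULT_MARKERS))
    return SpotExpression(table, obs, DEFAULT_MARKERS), deg_truth
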