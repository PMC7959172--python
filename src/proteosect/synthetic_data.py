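"""Synthetic two-group abundance matrices with known ground truth.

The generator emulates the structure of a label-free tumour proteome
comparison: a few thousand proteins over two groups of 20 samples, log2
abundances spanning roughly 20-30, a planted subset of differentially
abundant proteins, and a mixture of completely-random (MCAR) and
left-censored intensity-dependent (MNAR) missingness. Proteins are
statistically independent of each other; the dedicated network generators
below plant correlation structure for the co-expression/hub stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, GeneSetCollection

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_complete",
    "apply_missingness",
    "simulate",
    "generate_correlated_blocks",
    "generate_hub_network",
    "toy_gene_sets",
]

OBSERVED, MCAR, MNAR = "observed", "mcar", "mnar"


@dataclass
class SyntheticSpec:
    """Generation parameters; the defaults are the pipeline's study conditions.

    ``base_mean_range`` and ``protein_sd_range`` are log2 units before
    centering: per-protein means uniform on 20-30 (a realistic LFQ log2
    dynamic range) and per-protein standard deviations uniform on 0.5-1.5
    (typical biological variability across patient tumours). 10% of proteins
    carry a +2 log2 shift in group A. Missingness is 2% MCAR everywhere plus
    50% censoring below the global lower quartile of abundance.
    """

    n_proteins: int = 4000
    n_per_group: int = 20
    base_mean_range: tuple[float, float] = (20.0, 30.0)
    protein_sd_range: tuple[float, float] = (0.5, 1.5)
    frac_de: float = 0.1
    effect_log2: float = 2.0
    mcar_rate: float = 0.02
    mnar_quantile: float = 0.25
    mnar_rate: float = 0.5
    seed: int = 0
    group_labels: tuple[str, str] = ("COAD", "READ")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("frac_de", "mcar_rate", "mnar_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.mnar_quantile < 1.0):
            raise ValueError("mnar_quantile must lie in (0, 1)")
        if not np.isfinite(self.effect_log2):
            raise ValueError("effect_log2 must be finite")
        lo, hi = self.base_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("invalid base_mean_range")
        lo, hi = self.protein_sd_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid protein_sd_range")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated matrix."""

    complete_values: np.ndarray
    de_labels: np.ndarray
    missing_mechanism: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing_mechanism is None:
            self.missing_mechanism = np.full(
                self.complete_values.shape, OBSERVED, dtype=object
            )


def _sample_ids(spec: SyntheticSpec) -> tuple[list[str], dict[str, str]]:
    a, b = spec.group_labels
    ids = [f"{a}_{i + 1:02d}" for i in range(spec.n_per_group)] + [
        f"{b}_{i + 1:02d}" for i in range(spec.n_per_group)
    ]
    group_of = {s: (a if s.startswith(f"{a}_") else b) for s in ids}
    return ids, group_of


def generate_complete(spec: SyntheticSpec) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Draw a complete (no missing cells) matrix plus its truth record.

    Per protein i: mean mu_i ~ U(base_mean_range), sd sigma_i ~
    U(protein_sd_range), cells ~ N(mu_i, sigma_i); the planted differential
    proteins get ``effect_log2`` added to their group-A mean. Fully
    reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_proteins, 2 * spec.n_per_group
    mu = rng.uniform(*spec.base_mean_range, size=n)
    sd = rng.uniform(*spec.protein_sd_range, size=n)
    n_de = int(round(spec.frac_de * n))
    de = np.zeros(n, dtype=bool)
    de[rng.choice(n, size=n_de, replace=False)] = True
    values = rng.normal(mu[:, None], sd[:, None], size=(n, m))
    values[de, : spec.n_per_group] += spec.effect_log2
    protein_ids = [f"P{i + 1:05d}" for i in range(n)]
    sample_ids, group_of = _sample_ids(spec)
    matrix = AbundanceMatrix(
        protein_ids, sample_ids, group_of, values, np.zeros((n, m), dtype=bool)
    )
    return matrix, SyntheticTruth(values.copy(), de)


def apply_missingness(
    complete: AbundanceMatrix, truth: SyntheticTruth, spec: SyntheticSpec
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Censor a complete matrix: MCAR everywhere, MNAR below a global quantile.

    Each cell independently goes missing with probability ``mcar_rate``;
    otherwise, if its value lies below the global ``mnar_quantile`` of all
    values, it goes missing with probability ``mnar_rate``. The mechanism is
    recorded per cell.
    """
    if complete.missing_mask.any():
        raise ValueError("apply_missingness expects a complete matrix")
    rng = np.random.default_rng([spec.seed, 1])
    v = complete.values
    u_mcar = rng.random(v.shape)
    u_mnar = rng.random(v.shape)
    cutoff = np.quantile(v, spec.mnar_quantile)
    mcar = u_mcar < spec.mcar_rate
    mnar = ~mcar & (v < cutoff) & (u_mnar < spec.mnar_rate)
    mechanism = np.full(v.shape, OBSERVED, dtype=object)
    mechanism[mcar] = MCAR
    mechanism[mnar] = MNAR
    mask = mcar | mnar
    out = AbundanceMatrix(
        list(complete.protein_ids),
        list(complete.sample_ids),
        dict(complete.group_of),
        v.copy(),
        mask,
    )
    return out, SyntheticTruth(truth.complete_values, truth.de_labels, mechanism)


def simulate(
    spec: SyntheticSpec, *, center: bool = True
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Generate, optionally per-sample median-center, then censor.

    Centering happens on the complete matrix (before censoring) so that the
    recorded truth and the observed data live on one common scale and the
    left-censored missing values peak below zero, as they do on centered
    real data.
    """
    matrix, truth = generate_complete(spec)
    if center:
        med = np.median(matrix.values, axis=0)
        matrix.values = matrix.values - med[None, :]
        truth = SyntheticTruth(matrix.values.copy(), truth.de_labels)
    return apply_missingness(matrix, truth, spec)


# ---------------------------------------------------------------------------
# dedicated generators for the co-expression network stage
# ---------------------------------------------------------------------------

def generate_correlated_blocks(
    block_sizes: tuple[int, ...] = (30, 20),
    n_samples: int = 40,
    within_r: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Node-by-sample data with planted correlation blocks.

    Nodes within a block share a latent factor giving pairwise correlation
    ~``within_r``; cross-block correlation is ~0. Returns (data, block label
    per node).
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(block_sizes):
        latent = rng.normal(size=n_samples)
        load = np.sqrt(within_r)
        res = np.sqrt(1.0 - within_r)
        for _ in range(size):
            rows.append(load * latent + res * rng.normal(size=n_samples) * noise_sd)
            labels.append(b)
    ids = [f"N{i + 1:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids, columns=[f"S{j + 1:02d}" for j in range(n_samples)]), np.array(labels)


def generate_hub_network(
    n_nodes: int = 50,
    n_samples: int = 40,
    frac_loaded: float = 0.3,
    hub_noise_sd: float = 0.15,
    loading: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """Plant one hub driving a latent factor loaded by a fraction of nodes.

    The hub is the latent factor plus a small noise term; ``frac_loaded`` of
    the remaining nodes load on the factor with coefficient ``loading``; the
    rest are independent noise. Returns (data, hub node id).
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n_samples)
    rows = [latent + hub_noise_sd * rng.normal(size=n_samples)]
    n_loaded = int(round(frac_loaded * (n_nodes - 1)))
    res = np.sqrt(max(1.0 - loading**2, 0.0))
    for _ in range(n_loaded):
        rows.append(loading * latent + res * rng.normal(size=n_samples))
    for _ in range(n_nodes - 1 - n_loaded):
        rows.append(rng.normal(size=n_samples))
    ids = [f"N{i + 1:03d}" for i in range(n_nodes)]
    df = pd.DataFrame(
        rows, index=ids, columns=[f"S{j + 1:02d}" for j in range(n_samples)]
    )
    return df, ids[0]


def toy_gene_sets(
    protein_ids: list[str],
    n_sets: int = 6,
    set_size: int = 15,
    seed: int = 0,
) -> GeneSetCollection:
    """Small random gene sets over the given identifiers, for tests and demos."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(protein_ids)
    if set_size >= len(ids):
        raise ValueError("set_size must be smaller than the identifier universe")
    sets, desc = {}, {}
    for i in range(n_sets):
        name = f"SET{i + 1:02d}"
        members = rng.choice(ids, size=set_size, replace=False)
        sets[name] = sorted(members.tolist())
        desc[name] = "synthetic toy gene set"
    return GeneSetCollection(sets, desc)
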