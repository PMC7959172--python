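"""Shared domain types and readers/writers for the pipeline's external formats.

The pipeline works on a protein-by-sample abundance matrix (tab-delimited
text, LFQ-style intensities on log2 scale), a two-column sample annotation
mapping each sample to one of exactly two groups, and gene-set collections
in the standard GMT format.

Scale convention: all internal computation runs on log2-transformed,
per-sample median-centered abundances. On centered data the low-abundance
(left-censored) missing values sit below zero, which is the premise of the
sectionalized imputation scheme.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "GeneSetCollection",
    "PipelineConfig",
    "read_abundance_matrix",
    "read_gmt",
    "write_table",
    "write_abundance_matrix",
    "center_samples",
]

#: Cell contents treated as "not quantified" when reading matrices.
NA_STRINGS = ("", "NA", "NaN", "nan", "na")


@dataclass
class AbundanceMatrix:
    """Protein x sample log2 abundances with an explicit missing-cell mask.

    ``values`` carries ``NaN`` exactly where ``missing_mask`` is True, so a
    masked cell can never silently be read as a number.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    group_of: dict[str, str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = len(self.protein_ids), len(self.sample_ids)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} proteins x {m} samples"
            )
        if self.missing_mask.shape != (n, m):
            raise ValueError("missing_mask shape does not match values")
        if len(set(self.protein_ids)) != n:
            raise ValueError("duplicate protein ids")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample ids")
        missing_ann = [s for s in self.sample_ids if s not in self.group_of]
        if missing_ann:
            raise ValueError(f"samples absent from annotation: {missing_ann}")
        labels = self.group_labels
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        for g in labels:
            if len(self.columns_of(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        # enforce the mask/value contract
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValueError("non-masked cell carries NaN")

    @property
    def group_labels(self) -> tuple[str, ...]:
        """The two group labels, in order of first appearance among samples."""
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def columns_of(self, group: str) -> np.ndarray:
        """Column indices of the samples in ``group``."""
        return np.array(
            [j for j, s in enumerate(self.sample_ids) if self.group_of[s] == group],
            dtype=int,
        )

    def observed_values(self) -> np.ndarray:
        """1-D array of all non-missing cell values."""
        return self.values[~self.missing_mask]

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            list(self.protein_ids),
            list(self.sample_ids),
            dict(self.group_of),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def subset_proteins(self, keep: Iterable[str]) -> "AbundanceMatrix":
        keep = list(keep)
        index = {p: i for i, p in enumerate(self.protein_ids)}
        rows = np.array([index[p] for p in keep], dtype=int)
        return AbundanceMatrix(
            keep,
            list(self.sample_ids),
            dict(self.group_of),
            self.values[rows],
            self.missing_mask[rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )


@dataclass
class GeneSetCollection:
    """Named gene sets plus their free-text descriptions."""

    sets: dict[str, list[str]]
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(members))
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with the published defaults.

    The imputation constants (threshold multiplier 2, shift 1.8, shrink 0.3),
    the missingness filter counts (16, 18, 8 for groups of 20), the fold-change
    window (1.5 / 0.67), the significance levels (0.05 for the final test,
    0.1 for the normality/variance gates), the soft-thresholding power (5),
    the module count (2) and the hub centrality cut (30) follow the published
    analysis; everything is overridable.
    """

    threshold_multiplier: float = 2.0
    shift_factor: float = 1.8
    shrink_factor: float = 0.3
    knn_k: int = 10
    discard_count: int = 16
    flag_high_count: int = 18
    flag_low_count: int = 8
    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha_dep: float = 0.05
    alpha_gate: float = 0.1
    soft_power: int = 5
    n_modules: int = 2
    centrality_cut: float = 30.0
    ssgsea_alpha: float = 0.25
    rng_seed: int = 0
    # implementation options
    welch: bool = False              # Welch t instead of pooled-variance Student
    zero_fill_literal: bool = False  # benchmark zero_fill uses literal 0
    zeros_are_missing: bool = True   # treat 0 cells in input files as missing

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValueError(
                f"fold-change window must satisfy fc_down < 1 < fc_up, "
                f"got fc_down={self.fc_down}, fc_up={self.fc_up}"
            )
        for name in ("alpha_dep", "alpha_gate", "ssgsea_alpha"):
            v = getattr(self, name)
            if name == "ssgsea_alpha":
                if v < 0:
                    raise ValueError(f"{name} must be >= 0, got {v}")
            elif not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.soft_power < 1:
            raise ValueError(f"soft_power must be >= 1, got {self.soft_power}")
        if self.knn_k < 1:
            raise ValueError(f"knn_k must be >= 1, got {self.knn_k}")
        if self.shrink_factor < 0:
            raise ValueError("shrink_factor must be >= 0")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        for name in ("discard_count", "flag_high_count", "flag_low_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _parse_cell(text: str, zeros_are_missing: bool) -> float:
    t = text.strip()
    if t in NA_STRINGS:
        return np.nan
    v = float(t)
    if zeros_are_missing and v == 0.0:
        return np.nan
    return v


def read_abundance_matrix(
    path,
    annotation_path,
    *,
    linear_scale: bool = False,
    zeros_are_missing: bool = True,
) -> AbundanceMatrix:
    """Read a tab-delimited abundance matrix plus its sample annotation.

    The matrix file has protein ids in the first column and sample ids in the
    header row; blank, ``NA``, ``NaN`` and (by default) ``0`` cells are
    missing. The annotation file maps sample id -> group label (two columns,
    no header required). With ``linear_scale`` the values are log2-transformed
    on read; otherwise they are taken as already log2.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"{path}: duplicate sample id in header")
        protein_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            protein_ids.append(parts[0])
            rows.append([_parse_cell(c, zeros_are_missing) for c in parts[1:]])
    if len(set(protein_ids)) != len(protein_ids):
        dup = sorted({p for p in protein_ids if protein_ids.count(p) > 1})
        raise ValueError(f"{path}: duplicate protein ids: {dup[:5]}")
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    if linear_scale:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.log2(values)
        values[~np.isfinite(values)] = np.nan
    mask = np.isnan(values)

    ann = pd.read_csv(
        annotation_path, sep="\t", header=None, dtype=str, comment="#"
    )
    if ann.shape[1] < 2:
        raise ValueError(f"{annotation_path}: need two columns (sample, group)")
    first = (ann.iloc[0, 0], ann.iloc[0, 1])
    if first[0] not in sample_ids and str(first[0]).lower() in ("sample", "sample_id"):
        ann = ann.iloc[1:]
    group_of = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    return AbundanceMatrix(protein_ids, sample_ids, group_of, values, mask)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB member...

    Duplicate members within a line are collapsed (first occurrence kept);
    a duplicate set name or a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = list(dict.fromkeys(members))
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_table(records: pd.DataFrame, path, *, sort_by=None) -> None:
    """Write a tabular result as deterministic tab-delimited text.

    Rows are sorted by ``sort_by`` (default: the index), columns keep their
    given order, and the same records always produce byte-identical files.
    """
    df = records.copy()
    if sort_by is not None:
        df = df.sort_values(list(np.atleast_1d(sort_by)), kind="mergesort")
    else:
        df = df.sort_index(kind="mergesort")
    # default float repr is the shortest round-trip form: full precision,
    # deterministic, and read back bit-identically
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_abundance_matrix(matrix: AbundanceMatrix, path, annotation_path=None) -> None:
    """Write a matrix (missing cells blank) and optionally its annotation."""
    df = matrix.to_dataframe()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", lineterminator="\n", na_rep="")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.group_of[s]}\n")


def center_samples(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, np.ndarray]:
    """Subtract each sample's observed median; returns (centered, offsets).

    Centering places the bulk of each sample at zero so that the global
    down-shift imputation parameters and Threshold1 are comparable across
    samples.
    """
    out = matrix.copy()
    offsets = np.nanmedian(np.where(out.missing_mask, np.nan, out.values), axis=0)
    if np.isnan(offsets).any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(np.isnan(offsets))]
        raise ValueError(f"samples with no observed values: {bad}")
    out.values = out.values - offsets[None, :]
    out.values[out.missing_mask] = np.nan
    return out, offsets
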