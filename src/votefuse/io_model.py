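"""Data containers, readers/writers and validation for cohort tables.

The package works on three aligned pieces of data per cohort: case/control
labels, a genotype table of biallelic SNP calls (unordered allele pairs such
as ``AA``/``AT``/``TT``, with explicit missing calls), and a cytokine table of
non-negative serum concentrations in pg/mL.  Everything downstream (encoding,
normalization, QC, the ensemble) consumes these containers.

On-disk dialects
----------------
* genotype TSV: first column sample id, header = marker ids, cells are
  two-letter allele pairs or a missing token (``NN`` by default; ``00`` and
  ``--`` are also recognized);
* VCF v4.x (read-only import, biallelic SNP records only);
* cytokine CSV/TSV: first column sample id, header = analyte names;
* labels: two-column CSV ``sample_id,label`` with labels ``case``/``control``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
LABELS = (CASE, CONTROL)

#: tokens recognized as a missing genotype call on input
DEFAULT_MISSING_TOKENS = ("NN", "00", "--")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one biallelic marker."""

    marker_id: str
    chromosome: str = "0"
    alleles: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.alleles) > 2:
            raise ValidationError(
                f"marker {self.marker_id!r} has >2 alleles: {self.alleles}"
            )


@dataclass
class RawGenotypeTable:
    """Samples x markers table of unordered allele-pair calls.

    ``calls`` holds normalized two-letter strings with the letters sorted
    (so ``TA`` and ``AT`` are the same call) and ``None`` for missing.
    """

    calls: pd.DataFrame
    markers: dict[str, MarkerInfo] = field(default_factory=dict)
    rejected: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if not self.markers:
            self.markers = {m: MarkerInfo(m) for m in self.calls.columns}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    def marker_calls(self, marker_id: str) -> pd.Series:
        return self.calls[marker_id]


@dataclass
class RawCytokineTable:
    """Samples x analytes table of non-negative concentrations (pg/mL)."""

    concentrations: pd.DataFrame

    def __post_init__(self):
        df = self.concentrations
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        neg = df.lt(0)
        if neg.any().any():
            r, c = np.argwhere(neg.to_numpy())[0]
            raise ValidationError(
                f"negative concentration at sample {df.index[r]!r}, "
                f"analyte {df.columns[c]!r}: {df.iat[r, c]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)


@dataclass
class LabeledCohort:
    """Sample ids + case/control labels, with optionally attached tables."""

    sample_ids: list[str]
    labels: pd.Series
    genotype: Optional[RawGenotypeTable] = None
    cytokine: Optional[RawCytokineTable] = None

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("cohort sample ids are not unique")
        self.labels = self.labels.reindex(self.sample_ids)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValidationError(f"samples without a label: {missing}")
        bad = sorted(set(self.labels) - set(LABELS))
        if bad:
            raise ValidationError(f"labels must be one of {LABELS}; got {bad}")
        for tbl in (self.genotype, self.cytokine):
            if tbl is not None and list(tbl.sample_ids) != self.sample_ids:
                raise ValidationError(
                    "attached table does not cover exactly the cohort samples "
                    "in cohort order; use attach_and_align()"
                )

    @property
    def case_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])

    @property
    def n_cases(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == CONTROL).sum())


@dataclass
class RunConfig:
    """Run configuration for the integration pipeline.

    ``sampling_size`` is the total balanced draw (half cases, half controls);
    ``sampling_time`` is N, the cytokine pool size — the genotype pool gets
    K = N + 1 so the fused vote count K + N is odd and ties are impossible.
    """

    sampling_size: int = 40
    sampling_time: int = 25
    classifier: str = "svm_rbf"
    seed: int = 0
    grid: Optional[tuple[int, int, int, int, int, int]] = None  # size min/max/step, time min/max/step
    ld_r2: float = 0.8
    qc_missing_frac: float = 0.05
    qc_zero_frac: float = 0.05
    t_alpha: float = 0.05
    corner_cutoff: float = 0.9

    def __post_init__(self):
        from .base_classifiers import METHODS  # local import to avoid a cycle

        if self.sampling_size % 2 or self.sampling_size <= 0:
            raise ValidationError("sampling_size must be an even positive integer")
        if self.sampling_time < 1:
            raise ValidationError("sampling_time must be >= 1")
        if self.classifier not in METHODS:
            raise ValidationError(
                f"unknown classifier {self.classifier!r}; choose from {sorted(METHODS)}"
            )
        for name in ("qc_missing_frac", "qc_zero_frac", "t_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1); got {v}")
        if not 0 < self.ld_r2 <= 1:
            raise ValidationError(f"ld_r2 must be in (0,1]; got {self.ld_r2}")
        if not 0.5 < self.corner_cutoff < 1:
            raise ValidationError(
                f"corner_cutoff must be in (0.5,1); got {self.corner_cutoff}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if data.get("grid") is not None:
            data["grid"] = tuple(data["grid"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if d["grid"] is not None:
            d["grid"] = list(d["grid"])
        return d


# ---------------------------------------------------------------------------
# call normalization
# ---------------------------------------------------------------------------

def normalize_call(cell, missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS):
    """Map a raw genotype cell to a sorted two-letter call or None."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    s = str(cell).strip().upper()
    if s == "" or s in missing_tokens:
        return None
    if len(s) != 2 or not s.isalpha():
        raise ValidationError(f"malformed genotype call {cell!r}")
    return "".join(sorted(s))


def _collect_markers(
    calls: pd.DataFrame, chromosome_map: Optional[dict[str, str]]
) -> tuple[pd.DataFrame, dict[str, MarkerInfo], list[dict]]:
    """Validate biallelicity; reject markers with >2 distinct allele letters."""
    markers: dict[str, MarkerInfo] = {}
    rejected: list[dict] = []
    keep: list[str] = []
    for m in calls.columns:
        col = calls[m]
        alleles = sorted({a for call in col.dropna() for a in call})
        if len(alleles) > 2:
            rejected.append({"marker_id": m, "reason": f">2 alleles: {alleles}"})
            warnings.warn(f"marker {m!r} rejected: >2 alleles {alleles}")
            continue
        chrom = chromosome_map.get(m, "0") if chromosome_map else "0"
        markers[m] = MarkerInfo(m, chrom, tuple(alleles))
        keep.append(m)
    return calls[keep], markers, rejected


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotype_table(
    path: str | Path,
    format: Literal["tsv", "vcf"] = "tsv",
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    transpose: bool = False,
    chromosome_map: Optional[dict[str, str]] = None,
) -> RawGenotypeTable:
    """Read a genotype table from TSV (samples x markers) or VCF.

    TSV orientation is samples-as-rows; pass ``transpose=True`` for
    markers-as-rows files.  VCF import keeps biallelic SNP records only and
    treats phased and unphased genotypes identically (unordered pairs).
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        raw = raw.T
    raw.index.name = None
    raw.columns.name = None
    try:
        calls = raw.apply(
            lambda col: col.map(lambda c: normalize_call(c, missing_tokens))
        )
    except ValidationError as exc:
        # locate the offending cell for a line-addressed message
        for i, (sid, row) in enumerate(raw.iterrows(), start=2):
            for m, cell in row.items():
                try:
                    normalize_call(cell, missing_tokens)
                except ValidationError:
                    raise ValidationError(
                        f"{path}: line {i} (sample {sid!r}, marker {m!r}): {exc}"
                    ) from None
        raise
    calls = calls.astype(object).where(calls.notna(), None)
    calls, markers, rejected = _collect_markers(calls, chromosome_map)
    return RawGenotypeTable(calls, markers, rejected)


def _read_vcf(path: Path) -> RawGenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, list] = {}
    markers: dict[str, MarkerInfo] = {}
    rejected: list[dict] = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            rejected.append(
                {"marker_id": var.ID or f"{var.CHROM}:{var.POS}",
                 "reason": "not a biallelic SNP"}
            )
            continue
        mid = var.ID or f"{var.CHROM}:{var.POS}"
        alleles = (var.REF, var.ALT[0])
        col = []
        for gt in var.genotypes:  # [a0, a1, phased]
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                col.append(None)
            else:
                col.append("".join(sorted(alleles[a0] + alleles[a1])))
        cols[mid] = col
        markers[mid] = MarkerInfo(mid, str(var.CHROM), tuple(sorted(alleles)))
    calls = pd.DataFrame(cols, index=samples, dtype=object)
    calls = calls.where(calls.notna(), None)
    return RawGenotypeTable(calls, markers, rejected)


def read_cytokine_table(path: str | Path) -> RawCytokineTable:
    """Read a cytokine concentration table (CSV or TSV by file suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.apply(pd.to_numeric, errors="raise").astype(float)
    df.index.name = None
    df.columns.name = None
    return RawCytokineTable(df)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns sample_id,label")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str), name="label")
    return s


# ---------------------------------------------------------------------------
# writers (round-trip safe at the declared decimal formatting)
# ---------------------------------------------------------------------------

def write_genotype_table(
    table: RawGenotypeTable, path: str | Path, missing_token: str = "NN"
) -> None:
    out = table.calls.copy()
    out = out.where(out.notna(), missing_token)
    out.to_csv(path, sep="\t", index_label="sample_id")


def write_cytokine_table(table: RawCytokineTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.concentrations.to_csv(path, sep=sep, index_label="sample_id")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "label": labels.values}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def attach_and_align(
    cohort: LabeledCohort,
    genotype: Optional[RawGenotypeTable] = None,
    cytokine: Optional[RawCytokineTable] = None,
) -> LabeledCohort:
    """Reindex tables to the cohort's sample order and attach them.

    Samples present in the cohort but absent from a table get an all-missing
    row (reported via warning); a table sharing no sample with the cohort is
    an error, as is a duplicated sample id.
    """
    ids = cohort.sample_ids
    geno = cyto = None
    if genotype is not None:
        inter = set(ids) & set(genotype.sample_ids)
        if not inter:
            raise ValidationError("genotype table shares no sample with cohort")
        filled = sorted(set(ids) - set(genotype.sample_ids))
        if filled:
            warnings.warn(f"samples without genotype rows (all-missing fill): {filled}")
        calls = genotype.calls.reindex(ids)
        calls = calls.astype(object).where(calls.notna(), None)
        geno = RawGenotypeTable(calls, dict(genotype.markers), list(genotype.rejected))
    if cytokine is not None:
        inter = set(ids) & set(cytokine.sample_ids)
        if not inter:
            raise ValidationError("cytokine table shares no sample with cohort")
        filled = sorted(set(ids) - set(cytokine.sample_ids))
        if filled:
            warnings.warn(f"samples without cytokine rows (all-missing fill): {filled}")
        cyto = RawCytokineTable(cytokine.concentrations.reindex(ids))
    return LabeledCohort(ids, cohort.labels, geno, cyto)
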