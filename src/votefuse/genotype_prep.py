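"""Genotype preprocessing: risk-allele encoding, normalization, LD pruning.

At each biallelic marker the *risk allele* is the allele with the higher
frequency among case samples.  Calls become additive dosages of the risk
allele (homozygote 2, heterozygote 1, other homozygote 0) and are then
normalized the EIGENSTRAT way: subtract the training mean and divide by
sqrt(p(1-p)) with p the posterior risk-allele frequency estimate
p = (1 + sum(g)) / (2 + 2n) over the n non-missing training genotypes.
Missing calls become exactly 0.0 *after* normalization, i.e. they sit at the
training mean.  Test cohorts reuse the training statistics unchanged.

Markers in high linkage disequilibrium are pruned greedily to avoid
multicollinearity: r-squared is computed from two-locus haplotype frequencies
estimated by EM under Hardy-Weinberg equilibrium, and a marker is dropped
when r2 >= threshold against an already-kept marker on the same chromosome.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import CASE, CONTROL, RawGenotypeTable, ValidationError

MISSING = None
#: markers with sqrt(p(1-p)) below this are treated as monomorphic and dropped
MONOMORPHIC_SCALE = 1e-12


@dataclass
class MarkerEncoding:
    """Per-marker risk-allele assignment and training normalization stats."""

    marker_id: str
    risk_allele: str
    other_allele: str
    train_mean: float = float("nan")
    train_allele_freq: float = float("nan")
    scale: float = float("nan")
    constant_in_training: bool = False

    def normalize(self, g: float) -> float:
        return (g - self.train_mean) / self.scale


@dataclass
class EncodedGenotypeMatrix:
    """Normalized samples x markers matrix; missing entries are exactly 0.0."""

    values: pd.DataFrame
    encodings: dict[str, MarkerEncoding]
    missing_mask: pd.DataFrame

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("encoded genotype matrix contains non-finite values")


@dataclass
class LdPruneReport:
    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped_id, partner_id, r2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["dropped_id", "partner_id", "r2"])


# ---------------------------------------------------------------------------
# risk-allele determination and dosage encoding
# ---------------------------------------------------------------------------

def _allele_counts(calls: pd.Series) -> Counter:
    c: Counter = Counter()
    for call in calls.dropna():
        c[call[0]] += 1
        c[call[1]] += 1
    return c


def determine_risk_allele(
    marker_calls: pd.Series, labels: pd.Series
) -> tuple[str, str]:
    """Pick (risk_allele, other_allele) for one marker.

    Risk = allele with strictly higher frequency among non-missing case
    calls.  An exact 0.5 tie is broken by the lower control frequency, then
    lexicographically — deterministic and label-driven.
    """
    case_counts = _allele_counts(marker_calls[labels == CASE])
    if not case_counts:
        raise ValidationError(
            f"marker {marker_calls.name!r}: all case calls missing — unencodable"
        )
    all_alleles = sorted(_allele_counts(marker_calls))
    if len(all_alleles) > 2:
        raise ValidationError(
            f"marker {marker_calls.name!r} is not biallelic: {all_alleles}"
        )
    if len(all_alleles) == 1:
        # monomorphic across the cohort: risk is the observed allele; there is
        # no observed alternative, record a placeholder other allele
        a = all_alleles[0]
        return a, "." if a != "." else "-"
    a, b = all_alleles
    fa = case_counts[a] / sum(case_counts.values())
    if fa > 0.5:
        return a, b
    if fa < 0.5:
        return b, a
    ctrl_counts = _allele_counts(marker_calls[labels == CONTROL])
    tot = sum(ctrl_counts.values())
    ca = ctrl_counts[a] / tot if tot else 0.5
    cb = ctrl_counts[b] / tot if tot else 0.5
    if ca < cb:
        return a, b
    if cb < ca:
        return b, a
    return a, b  # full tie: lexicographic


def encode_numeric(call: Optional[str], enc: MarkerEncoding):
    """Risk-allele dosage of one call: 2/1/0, missing propagated."""
    if call is None:
        return MISSING
    g = 0
    for a in call:
        if a == enc.risk_allele:
            g += 1
        elif a != enc.other_allele:
            raise ValidationError(
                f"marker {enc.marker_id!r}: foreign allele {a!r} in call {call!r}"
            )
    return g


def encode_table(
    table: RawGenotypeTable, encodings: dict[str, MarkerEncoding]
) -> pd.DataFrame:
    """Dosage-encode a whole table (float matrix, NaN for missing)."""
    out = {}
    for mid in table.marker_ids:
        if mid not in encodings:
            raise ValidationError(f"marker {mid!r} absent from encodings")
        enc = encodings[mid]
        out[mid] = [
            np.nan if (g := encode_numeric(call, enc)) is MISSING else float(g)
            for call in table.calls[mid]
        ]
    return pd.DataFrame(out, index=table.calls.index, dtype=float)


# ---------------------------------------------------------------------------
# EIGENSTRAT normalization
# ---------------------------------------------------------------------------

def fit_normalization(
    train_numeric: pd.Series, enc: MarkerEncoding
) -> MarkerEncoding:
    """Complete an encoding with training mean / allele frequency / scale."""
    g = train_numeric.dropna().to_numpy(dtype=float)
    n = g.size
    if n < 2:
        raise ValidationError(
            f"marker {enc.marker_id!r}: <2 non-missing training genotypes"
        )
    p = (1.0 + g.sum()) / (2.0 + 2.0 * n)
    scale = float(np.sqrt(p * (1.0 - p)))
    if scale < MONOMORPHIC_SCALE:
        raise ValidationError(
            f"marker {enc.marker_id!r}: effectively monomorphic (scale {scale:g})"
        )
    enc.train_mean = float(g.mean())
    enc.train_allele_freq = float(p)
    enc.scale = scale
    enc.constant_in_training = bool(np.ptp(g) == 0)
    return enc


def fit_encodings(
    table: RawGenotypeTable, labels: pd.Series
) -> tuple[dict[str, MarkerEncoding], list[dict]]:
    """Risk alleles + normalization stats for every encodable marker.

    Returns the encodings and a report of markers dropped as unencodable
    (all case calls missing, <2 training calls, or monomorphic scale).
    """
    encodings: dict[str, MarkerEncoding] = {}
    dropped: list[dict] = []
    for mid in table.marker_ids:
        calls = table.marker_calls(mid)
        try:
            risk, other = determine_risk_allele(calls, labels)
            enc = MarkerEncoding(mid, risk, other)
            numeric = pd.Series(
                [np.nan if (g := encode_numeric(c, enc)) is MISSING else float(g)
                 for c in calls],
                index=calls.index,
            )
            encodings[mid] = fit_normalization(numeric, enc)
        except ValidationError as exc:
            dropped.append({"marker_id": mid, "reason": str(exc)})
            warnings.warn(str(exc))
    return encodings, dropped


def apply_normalization(
    table: RawGenotypeTable, encodings: dict[str, MarkerEncoding]
) -> EncodedGenotypeMatrix:
    """Normalize any cohort with training-fitted encodings; missing -> 0.0."""
    numeric = encode_table(table, encodings)
    mask = numeric.isna()
    means = pd.Series({m: encodings[m].train_mean for m in numeric.columns})
    scales = pd.Series({m: encodings[m].scale for m in numeric.columns})
    values = (numeric - means) / scales
    values = values.where(~mask, 0.0)
    return EncodedGenotypeMatrix(values, encodings, mask)


def save_encodings(encodings: dict[str, MarkerEncoding], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({m: asdict(e) for m, e in encodings.items()}, indent=1)
    )


def load_encodings(path: str | Path) -> dict[str, MarkerEncoding]:
    data = json.loads(Path(path).read_text())
    return {m: MarkerEncoding(**d) for m, d in data.items()}


# ---------------------------------------------------------------------------
# linkage disequilibrium: two-locus EM r-squared and greedy pruning
# ---------------------------------------------------------------------------

def _dosage_pair(calls_a: pd.Series, calls_b: pd.Series):
    """Joint non-missing dosages (count of the lexicographically first allele)."""
    joint = pd.DataFrame({"a": calls_a, "b": calls_b}).dropna()
    if len(joint) < 5:
        raise ValidationError("pairwise_r2 requires >=5 jointly non-missing samples")

    def dosages(col: pd.Series) -> np.ndarray:
        alleles = sorted({a for call in col for a in call})
        if len(alleles) == 1:
            return np.full(len(col), 2)
        ref = alleles[0]
        return np.array([call.count(ref) for call in col])

    return dosages(joint["a"]), dosages(joint["b"])


def pairwise_r2(
    calls_a: pd.Series,
    calls_b: pd.Series,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """r2 between two markers from EM-estimated haplotype frequencies.

    Standard two-locus EM under HWE: every genotype pair except the double
    heterozygote resolves to known haplotypes; the double-het split between
    AB/ab and Ab/aB phases is iterated to convergence.  A marker monomorphic
    on the joint samples gives r2 = 0 with a warning.
    """
    ga, gb = _dosage_pair(calls_a, calls_b)
    n = ga.size
    pa = ga.sum() / (2 * n)
    pb = gb.sum() / (2 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        warnings.warn("marker monomorphic on joint samples; r2 defined as 0")
        return 0.0

    # fixed haplotype-count contributions (excluding double hets)
    n_dh = int(((ga == 1) & (gb == 1)).sum())
    c_AB = 2 * ((ga == 2) & (gb == 2)).sum() + ((ga == 2) & (gb == 1)).sum() \
        + ((ga == 1) & (gb == 2)).sum()
    c_Ab = 2 * ((ga == 2) & (gb == 0)).sum() + ((ga == 2) & (gb == 1)).sum() \
        + ((ga == 1) & (gb == 0)).sum()
    c_aB = 2 * ((ga == 0) & (gb == 2)).sum() + ((ga == 0) & (gb == 1)).sum() \
        + ((ga == 1) & (gb == 2)).sum()
    c_ab = 2 * ((ga == 0) & (gb == 0)).sum() + ((ga == 0) & (gb == 1)).sum() \
        + ((ga == 1) & (gb == 0)).sum()
    total = 2.0 * n

    x = 0.5  # P(double het is AB/ab phase)
    f_AB = f_ab = f_Ab = f_aB = 0.25
    for _ in range(max_iter):
        f_AB = (c_AB + x * n_dh) / total
        f_ab = (c_ab + x * n_dh) / total
        f_Ab = (c_Ab + (1 - x) * n_dh) / total
        f_aB = (c_aB + (1 - x) * n_dh) / total
        num = f_AB * f_ab
        den = num + f_Ab * f_aB
        x_new = 0.5 if den == 0 else num / den
        if abs(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    f_AB = (c_AB + x * n_dh) / total
    d = f_AB - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return float(min(max(r2, 0.0), 1.0))


def ld_prune(
    table: RawGenotypeTable,
    threshold: float = 0.8,
    priority: Optional[Sequence[str]] = None,
) -> LdPruneReport:
    """Greedy LD pruning at ``r2 >= threshold`` within chromosomes.

    Markers are scanned in ``priority`` order (ascending GWAS p-value if the
    caller has one; input order otherwise); each is dropped if it is in high
    LD with any already-kept marker on the same chromosome.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0,1]; got {threshold}")
    order = list(priority) if priority is not None else table.marker_ids
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    chrom = {m: table.markers[m].chromosome for m in table.marker_ids}
    for m in order:
        hit = None
        for k in kept:
            if chrom[k] != chrom[m]:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = pairwise_r2(table.marker_calls(m), table.marker_calls(k))
            if r2 >= threshold:
                hit = (m, k, r2)
                break
        if hit is None:
            kept.append(m)
        else:
            dropped.append(hit)
    return LdPruneReport(kept, dropped)
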