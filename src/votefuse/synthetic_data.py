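"""Synthetic case-control cohorts with the structure the method assumes.

The generator emulates the study design the package targets: a training set
of 42 cases / 42 controls and a test set of 73 cases / 52 controls; a
candidate panel of ~40 biallelic SNPs with case-enriched allele frequencies,
11 of which are planted high-LD duplicates of other panel markers; and a
29-analyte serum cytokine panel, 3 of which carry a true case shift.

Cases are a mixture of aetiological subgroups: a *genetic* subgroup whose
genotypes are drawn at elevated risk-allele frequencies, a *cytokine*
subgroup whose informative analytes are shifted, a *both* and a *neither*
subgroup.  This is the structure under which attribute-separated voting is
interesting: each attribute block recognizes its own subgroup.

Genotypes follow Hardy-Weinberg equilibrium within each stratum; control
frequencies come from the packaged marker presets (pooled genotype
frequencies of the 29-SNP study panel).  Cytokine concentrations are
log-normal (positive and right-skewed, as serum panels are).  Planted LD
duplicates are copy-with-flip-noise clones (flip probability 0.02 per
allele) of common markers, which keeps their r2 with the source well above
the default pruning threshold.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    CASE,
    CONTROL,
    LabeledCohort,
    RawCytokineTable,
    RawGenotypeTable,
    MarkerInfo,
    ValidationError,
)

# ---------------------------------------------------------------------------
# marker presets: pooled genotype frequencies of the 29-SNP panel
# (dbSNP id, chromosome, genotype:frequency triple)
# ---------------------------------------------------------------------------

_PANEL_PRESETS: list[tuple[str, str, tuple[tuple[str, float], ...]]] = [
    ("rs547984", "1", (("AA", 0.263), ("AC", 0.488), ("CC", 0.249))),
    ("rs1892116", "1", (("AA", 0.507), ("AG", 0.445), ("GG", 0.048))),
    ("rs4666488", "2", (("AA", 0.100), ("AG", 0.397), ("GG", 0.503))),
    ("rs2268794", "2", (("AA", 0.005), ("AT", 0.319), ("TT", 0.676))),
    ("rs7574012", "2", (("AA", 0.373), ("AG", 0.459), ("GG", 0.168))),
    ("rs1990702", "2", (("GG", 0.120), ("GA", 0.433), ("AA", 0.447))),
    ("rs10930437", "2", (("AA", 0.429), ("AG", 0.454), ("GG", 0.117))),
    ("rs779701", "3", (("AA", 0.490), ("AG", 0.413), ("GG", 0.097))),
    ("rs6550783", "3", (("AA", 0.412), ("AG", 0.442), ("GG", 0.146))),
    ("rs6550308", "3", (("GG", 0.215), ("GA", 0.488), ("AA", 0.297))),
    ("rs3922704", "3", (("CC", 0.034), ("CG", 0.254), ("GG", 0.712))),
    ("rs17279573", "4", (("GG", 0.120), ("GA", 0.483), ("AA", 0.397))),
    ("rs818725", "5", (("CC", 0.019), ("CG", 0.226), ("GG", 0.755))),
    ("rs11750584", "5", (("CC", 0.029), ("CG", 0.292), ("GG", 0.679))),
    ("rs9640055", "7", (("GG", 0.038), ("GA", 0.344), ("AA", 0.618))),
    ("rs2966712", "7", (("AA", 0.005), ("AG", 0.211), ("GG", 0.784))),
    ("rs411102", "9", (("GG", 0.749), ("GA", 0.242), ("AA", 0.009))),
    ("rs785054", "9", (("GG", 0.514), ("GA", 0.361), ("AA", 0.125))),
    ("rs7081455", "10", (("AA", 0.644), ("AC", 0.293), ("CC", 0.063))),
    ("rs4936221", "11", (("AA", 0.565), ("AC", 0.383), ("CC", 0.052))),
    ("rs610160", "11", (("AA", 0.693), ("AG", 0.262), ("GG", 0.045))),
    ("rs7961953", "12", (("GG", 0.522), ("GA", 0.397), ("AA", 0.081))),
    ("rs10492680", "13", (("GG", 0.005), ("GA", 0.187), ("AA", 0.808))),
    ("rs1571379", "14", (("AA", 0.440), ("AG", 0.454), ("GG", 0.106))),
    ("rs9788983", "17", (("AA", 0.770), ("AG", 0.215), ("GG", 0.015))),
    ("rs16940484", "18", (("GG", 0.469), ("GA", 0.450), ("AA", 0.081))),
    ("rs2864107", "19", (("GG", 0.684), ("GA", 0.301), ("AA", 0.015))),
    ("rs6115865", "20", (("AA", 0.125), ("AG", 0.428), ("GG", 0.447))),
    ("rs5765558", "22", (("AA", 0.287), ("AG", 0.478), ("GG", 0.235))),
]


@dataclass(frozen=True)
class GenotypePreset:
    """Pooled genotype frequencies for one panel marker."""

    marker_id: str
    chromosome: str
    genotype_freqs: tuple[tuple[str, float], ...]

    @property
    def alleles(self) -> tuple[str, str]:
        first = self.genotype_freqs[0][0][0]
        other = next(
            a for gt, _ in self.genotype_freqs for a in gt if a != first
        )
        return first, other

    @property
    def freqs(self) -> tuple[float, float, float]:
        return tuple(f for _, f in self.genotype_freqs)

    @property
    def allele_freq(self) -> float:
        """Frequency of the first-listed allele, from the genotype triple."""
        (f_hom1, f_het, _) = self.freqs
        return f_hom1 + 0.5 * f_het


def marker_panel_presets() -> dict[str, GenotypePreset]:
    """The packaged 29 marker presets keyed by dbSNP id."""
    return {
        mid: GenotypePreset(mid, chrom, gts) for mid, chrom, gts in _PANEL_PRESETS
    }


# ---------------------------------------------------------------------------
# simulation spec
# ---------------------------------------------------------------------------

#: case subgroups in the order of ``subgroup_fracs``
SUBGROUPS = ("genetic", "cytokine", "both", "neither")

#: cytokine analytes that carry a true case shift under the default spec
DEFAULT_INFORMATIVE_ANALYTES = ("FasLigand", "Eotaxin", "MIG")


@dataclass
class SimSpec:
    """Parameters of one synthetic cohort draw.

    Defaults mirror the emulated study: cohort sizes 42/42 train and 73/52
    test; 40 markers = 29 preset-frequency SNPs + 11 planted LD duplicates;
    29 cytokines of which 3 are informative.  ``snp_effects`` is a per-SNP
    (control freq p0, case freq p1) list for the non-duplicate markers;
    ``cytokine_effects`` a per-analyte (log-mean, log-SD, case log-shift).
    Case subgroup fractions are (genetic-only, cytokine-only, both, neither).
    """

    n_case_train: int = 42
    n_control_train: int = 42
    n_case_test: int = 73
    n_control_test: int = 52
    n_snps: int = 40
    snp_effects: Optional[list[tuple[float, float]]] = None
    missing_rate: float = 0.01
    n_planted_ld_duplicates: int = 11
    ld_flip_prob: float = 0.02
    n_cytokines: int = 29
    cytokine_effects: Optional[list[tuple[float, float, float]]] = None
    subgroup_fracs: tuple[float, float, float, float] = (0.5, 0.5, 0.0, 0.0)
    snp_effect_delta: float = 0.2
    cytokine_log_shift: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.subgroup_fracs) - 1.0) > 1e-9:
            raise ValidationError("subgroup_fracs must sum to 1")
        if any(f < 0 for f in self.subgroup_fracs):
            raise ValidationError("subgroup_fracs must be non-negative")
        for n in (self.n_case_train, self.n_control_train,
                  self.n_case_test, self.n_control_test):
            if n <= 0:
                raise ValidationError("cohort sizes must be positive")
        if self.n_planted_ld_duplicates >= self.n_snps:
            raise ValidationError("duplicates must be fewer than markers")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0,1)")


@dataclass
class SimulatedCohort:
    """Training and test cohorts with attached tables and a truth sidecar."""

    train: LabeledCohort
    test: LabeledCohort
    truth: dict = field(default_factory=dict)

    def write_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth, indent=1))


def _largest_remainder(n: int, fracs: Sequence[float]) -> list[int]:
    """Integer allocation of n over fractions; remainders by largest first."""
    raw = [n * f for f in fracs]
    base = [math.floor(x) for x in raw]
    leftover = n - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def _default_snp_effects(n_base: int, delta: float) -> list[tuple[float, float, GenotypePreset]]:
    presets = list(marker_panel_presets().values())
    out = []
    for i in range(n_base):
        preset = presets[i % len(presets)]
        p0 = preset.allele_freq
        p1 = min(p0 + delta, 0.95)
        out.append((p0, p1, preset))
    return out


def simulate_cohort(spec: SimSpec) -> SimulatedCohort:
    """Draw one full synthetic study (training + test cohorts)."""
    rng = np.random.default_rng(spec.seed)
    n_base = spec.n_snps - spec.n_planted_ld_duplicates

    if spec.snp_effects is not None:
        presets = list(marker_panel_presets().values())
        effects = [
            (p0, p1, presets[i % len(presets)])
            for i, (p0, p1) in enumerate(spec.snp_effects)
        ]
        if len(effects) != n_base:
            raise ValidationError(
                f"snp_effects must list {n_base} non-duplicate markers"
            )
    else:
        effects = _default_snp_effects(n_base, spec.snp_effect_delta)

    # marker metadata; repeated preset cycles get suffixed ids
    marker_ids, marker_meta = [], {}
    seen: dict[str, int] = {}
    for p0, p1, preset in effects:
        mid = preset.marker_id
        if mid in seen:
            seen[mid] += 1
            mid = f"{mid}.{seen[preset.marker_id]}"
        else:
            seen[mid] = 0
        marker_ids.append(mid)
        marker_meta[mid] = (p0, p1, preset)

    # duplicate sources: common markers only — LD between a common and a rare
    # variant is bounded low by construction, so duplicates of rare markers
    # would not reliably exceed the pruning threshold
    common = [m for m in marker_ids if 0.2 <= marker_meta[m][0] <= 0.8]
    if len(common) < spec.n_planted_ld_duplicates:
        common = marker_ids
    dup_sources = list(
        rng.choice(common, size=spec.n_planted_ld_duplicates, replace=False)
    )

    # sample ids, labels, subgroups
    def build_samples(prefix: str, n_case: int, n_control: int):
        ids = [f"{prefix}_case_{i+1:03d}" for i in range(n_case)] + [
            f"{prefix}_ctrl_{i+1:03d}" for i in range(n_control)
        ]
        labels = pd.Series(
            [CASE] * n_case + [CONTROL] * n_control, index=ids, name="label"
        )
        counts = _largest_remainder(n_case, spec.subgroup_fracs)
        subgroup = {}
        k = 0
        for grp, cnt in zip(SUBGROUPS, counts):
            for _ in range(cnt):
                subgroup[ids[k]] = grp
                k += 1
        for sid in ids[n_case:]:
            subgroup[sid] = "control"
        return ids, labels, subgroup

    tr_ids, tr_labels, tr_sub = build_samples(
        "tr", spec.n_case_train, spec.n_control_train
    )
    te_ids, te_labels, te_sub = build_samples(
        "te", spec.n_case_test, spec.n_control_test
    )
    all_ids = tr_ids + te_ids
    subgroup = {**tr_sub, **te_sub}
    genetic = np.array(
        [subgroup[s] in ("genetic", "both") for s in all_ids]
    )
    cyto_shifted = np.array(
        [subgroup[s] in ("cytokine", "both") for s in all_ids]
    )
    n_all = len(all_ids)

    # genotypes: HWE draws of risk-allele dosage per stratum
    calls = {}
    markers: dict[str, MarkerInfo] = {}
    dosages: dict[str, np.ndarray] = {}
    for mid in marker_ids:
        p0, p1, preset = marker_meta[mid]
        p = np.where(genetic, p1, p0)
        g = rng.binomial(2, p)
        dosages[mid] = g
        a_risk, a_other = preset.alleles
        calls[mid] = _dosage_to_calls(g, a_risk, a_other)
        markers[mid] = MarkerInfo(mid, preset.chromosome, tuple(sorted((a_risk, a_other))))

    dup_map = {}
    for j, src in enumerate(dup_sources, start=1):
        mid = f"{src}_ld{j}"
        p0, p1, preset = marker_meta[src]
        a_risk, a_other = preset.alleles
        src_g = dosages[src]
        # per-allele flip noise: each of the two allele copies flips w.p. flip_prob
        flips = rng.binomial(1, spec.ld_flip_prob, size=(n_all, 2))
        copy0 = (src_g >= 1).astype(int) ^ flips[:, 0]
        copy1 = (src_g == 2).astype(int) ^ flips[:, 1]
        g = copy0 + copy1
        calls[mid] = _dosage_to_calls(g, a_risk, a_other)
        markers[mid] = MarkerInfo(mid, preset.chromosome, tuple(sorted((a_risk, a_other))))
        dup_map[mid] = src

    calls_df = pd.DataFrame(calls, index=all_ids, dtype=object)
    if spec.missing_rate > 0:
        mask = rng.random(calls_df.shape) < spec.missing_rate
        calls_df = calls_df.mask(pd.DataFrame(mask, index=calls_df.index,
                                              columns=calls_df.columns), None)
    calls_df = calls_df.where(calls_df.notna(), None)

    # cytokines: log-normal, case shift only in cytokine subgroups
    if spec.cytokine_effects is not None:
        cyt_effects = list(spec.cytokine_effects)
        if len(cyt_effects) != spec.n_cytokines:
            raise ValidationError("cytokine_effects must cover n_cytokines analytes")
        analytes = [
            DEFAULT_INFORMATIVE_ANALYTES[i]
            if i < len(DEFAULT_INFORMATIVE_ANALYTES) and cyt_effects[i][2] != 0
            else f"analyte{i+1:02d}"
            for i in range(spec.n_cytokines)
        ]
    else:
        cyt_effects, analytes = [], []
        for i in range(spec.n_cytokines):
            mu = math.log(50.0) + 0.08 * i
            if i < 3:
                cyt_effects.append((mu, 0.5, spec.cytokine_log_shift))
                analytes.append(DEFAULT_INFORMATIVE_ANALYTES[i])
            else:
                cyt_effects.append((mu, 0.5, 0.0))
                analytes.append(f"analyte{i+1:02d}")

    conc = {}
    for name, (mu, sigma, shift) in zip(analytes, cyt_effects):
        z = rng.normal(size=n_all)
        logc = mu + sigma * z + shift * cyto_shifted
        conc[name] = np.exp(logc)
    conc_df = pd.DataFrame(conc, index=all_ids)

    def cohort(ids, labels):
        geno = RawGenotypeTable(
            calls_df.loc[ids].copy(), dict(markers)
        )
        cyto = RawCytokineTable(conc_df.loc[ids].copy())
        return LabeledCohort(list(ids), labels, geno, cyto)

    truth = {
        "subgroup": subgroup,
        "markers": {
            m: {"p0": marker_meta[m][0], "p1": marker_meta[m][1],
                "chromosome": markers[m].chromosome}
            for m in marker_ids
        },
        "ld_duplicates": dup_map,
        "informative_analytes": [
            a for a, (_, _, s) in zip(analytes, cyt_effects) if s != 0
        ],
        "seed": spec.seed,
    }
    return SimulatedCohort(cohort(tr_ids, tr_labels), cohort(te_ids, te_labels), truth)


def _dosage_to_calls(g: np.ndarray, risk: str, other: str) -> list[str]:
    lut = {
        0: "".join(sorted(other + other)),
        1: "".join(sorted(risk + other)),
        2: "".join(sorted(risk + risk)),
    }
    return [lut[int(x)] for x in g]


def pooled_genotype_table(sim: SimulatedCohort) -> RawGenotypeTable:
    """Train + test calls pooled, e.g. for panel-level LD pruning."""
    calls = pd.concat([sim.train.genotype.calls, sim.test.genotype.calls])
    return RawGenotypeTable(calls, dict(sim.train.genotype.markers))


# ---------------------------------------------------------------------------
# fixed QC cascade fixture
# ---------------------------------------------------------------------------

_QC_FIXTURE_SEED = 424273  # fixed: the fixture is a packaged artifact

#: planted analyte roles: 7 high-missing, 14 high-zero, 5 null, 3 strong
QC_FIXTURE_ROLES = ("fail",) * 7 + ("zero",) * 14 + ("null",) * 5 + ("strong",) * 3


def make_qc_fixture() -> tuple[RawCytokineTable, pd.Series]:
    """84-sample, 29-analyte cytokine table exercising the full QC cascade.

    Planted composition: 7 analytes with >5% missing cells (6 of 84), 14
    with >5% exact zeros (8 of 84), 5 with a null group effect and 3 with a
    strong effect (standardized mean difference >= 1.5).  The null analytes
    are built with identical case and control value multisets, so their t
    statistic is exactly zero; the cascade outcome (7 dropped for missing,
    14 for zeros, 5 non-significant, 3 kept) is deterministic.
    """
    rng = np.random.default_rng(_QC_FIXTURE_SEED)
    n_case = n_control = 42
    n = n_case + n_control
    ids = [f"s{i+1:02d}" for i in range(n)]
    labels = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=ids, name="label")

    cols = {}
    for i, role in enumerate(QC_FIXTURE_ROLES):
        name = f"C{i+1:02d}"
        base = np.exp(rng.normal(math.log(100.0), 0.3, size=n))
        if role == "fail":
            idx = rng.choice(n, size=6, replace=False)
            base[idx] = np.nan
        elif role == "zero":
            idx = rng.choice(n, size=8, replace=False)
            base[idx] = 0.0
        elif role == "null":
            vals = np.exp(rng.normal(math.log(100.0), 0.3, size=n_case))
            base[:n_case] = vals
            base[n_case:] = rng.permutation(vals)  # identical multisets: t == 0
        else:  # strong: case log-shift 1.2 (standardized difference >> 1.5)
            base[:n_case] *= math.exp(1.2)
        cols[name] = base
    table = RawCytokineTable(pd.DataFrame(cols, index=ids))
    return table, labels
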