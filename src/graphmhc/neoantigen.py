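"""Neoantigen load from missense variants and group comparisons.

A missense mutation in a protein yields the 9-mer windows that contain the
mutated residue; each (HLA allele, window) pair is scored by the binding
model, and a patient's neoantigen load is the number of pairs predicted to
bind.  Patients are split at the cohort median load into high/low groups and
compared by overall survival (Mantel-Cox log-rank) and by biomarker scores
(two-sided Mann-Whitney rank-sum).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from scipy.special import expit

from .featurize import featurize_pair

__all__ = [
    "PatientRecord",
    "GroupComparison",
    "nine_mer_windows",
    "neoantigen_load",
    "median_split",
    "logrank_test",
    "score_comparison",
    "log_affinity_transform",
    "sigmoid_affinity_transform",
    "analyze_cohort",
    "read_patient_table",
    "read_clinical_table",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientRecord:
    patient_id: str
    alleles: list[str]
    candidates: list[str]  # 9-mer neoantigen candidate peptides
    survival_time: float | None = None  # days
    event: bool | None = None
    stromal: float | None = None
    immune: float | None = None
    estimate: float | None = None

    def __post_init__(self):
        if self.survival_time is not None and self.survival_time < 0:
            raise ValueError(f"{self.patient_id}: negative survival time")
        for pep in self.candidates:
            if len(pep) != 9:
                raise ValueError(
                    f"{self.patient_id}: candidate {pep!r} is not a 9-mer"
                )


@dataclass
class GroupComparison:
    """High/low neoantigen-load group comparison results."""

    high_patients: list[str]
    low_patients: list[str]
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    score_tests: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "high_patients": self.high_patients,
            "low_patients": self.low_patients,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "score_tests": {
                k: {"statistic": v[0], "p": v[1]} for k, v in self.score_tests.items()
            },
        }


def nine_mer_windows(protein_seq: str, mutated_position: int) -> list[str]:
    """All 9-mer substrings containing the mutated residue, by start position.

    ``mutated_position`` is 1-based.  A protein shorter than 9 residues
    yields no window (with a warning): it cannot fill a class-I 9-mer.
    """
    L = len(protein_seq)
    if not 1 <= mutated_position <= L:
        raise ValueError(
            f"mutated position {mutated_position} outside sequence of length {L}"
        )
    if L < 9:
        logger.warning("sequence of length %d is shorter than 9; no windows", L)
        return []
    first = max(1, mutated_position - 8)
    last = min(mutated_position, L - 8)
    return [protein_seq[s - 1 : s + 8] for s in range(first, last + 1)]


def _pair_scores(model, allele_pseudo: str, peptides: list[str]) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        samples = [featurize_pair(allele_pseudo, pep) for pep in peptides]
        return np.asarray(model.predict_proba(samples))[:, 1]
    return np.array([float(model(allele_pseudo, pep)) for pep in peptides])


def neoantigen_load(
    patient: PatientRecord,
    model,
    mapping: dict[str, str],
    threshold: float = 0.5,
    count_unique_peptides: bool = False,
) -> int:
    """Number of (allele, candidate) pairs predicted to bind (prob >= threshold).

    ``model`` is either an estimator with ``predict_proba`` over featurized
    graph samples, or a callable ``(pseudo_sequence, peptide) -> probability``.
    By default every binding pair counts, so a peptide presented by two
    alleles counts twice; ``count_unique_peptides=True`` counts each peptide
    at most once.  Alleles missing from the pseudo-sequence map are skipped
    with a logged warning.
    """
    if not patient.candidates:
        return 0
    binding_peptides: set[str] = set()
    load = 0
    for allele in patient.alleles:
        if allele not in mapping:
            logger.warning(
                "%s: allele %s has no pseudo-sequence; skipped",
                patient.patient_id,
                allele,
            )
            continue
        probs = _pair_scores(model, mapping[allele], patient.candidates)
        hits = probs >= threshold
        load += int(hits.sum())
        binding_peptides.update(
            pep for pep, h in zip(patient.candidates, hits) if h
        )
    return len(binding_peptides) if count_unique_peptides else load


def median_split(loads) -> np.ndarray:
    """Boolean high-group mask: load strictly above the median (ties go low)."""
    loads = np.asarray(loads, dtype=float)
    if loads.size < 2:
        raise ValueError("median split needs at least 2 patients")
    high = loads > np.median(loads)
    if not high.any():
        logger.warning("degenerate median split: high group is empty")
    return high


def _censor(times, events, horizon_days):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if horizon_days is not None:
        over = times > horizon_days
        times = np.where(over, horizon_days, times)
        events = events & ~over
    return times, events


def logrank_test(
    times, events, groups, horizon_days: float | None = None
) -> tuple[float, float]:
    """Mantel-Cox log-rank chi-square (1 df) between two groups.

    ``groups`` is a boolean/0-1 array.  ``horizon_days`` applies
    administrative censoring (e.g. 1825 for 5-year survival).
    """
    groups = np.asarray(groups).astype(bool)
    times, events = _censor(times, events, horizon_days)
    if times.shape != groups.shape:
        raise ValueError("times and groups must align")
    if groups.all() or (~groups).all():
        raise ValueError("log-rank test needs two non-empty groups")
    res = _lifelines_logrank(
        times[groups], times[~groups], events[groups], events[~groups]
    )
    return float(res.test_statistic), float(res.p_value)


def score_comparison(scores, groups) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test of a biomarker between groups."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups).astype(bool)
    if groups.all() or (~groups).all():
        raise ValueError("comparison needs two non-empty groups")
    res = stats.mannwhitneyu(
        scores[groups], scores[~groups], alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)


def log_affinity_transform(affinity_nm) -> np.ndarray | float:
    """``1 - log(x)/log(50000)``: maps 1 nM -> 1 and 50000 nM -> 0."""
    x = np.asarray(affinity_nm, dtype=float)
    if np.any(x <= 0):
        raise ValueError("affinity must be positive")
    out = 1.0 - np.log(x) / math.log(50000.0)
    return float(out) if np.isscalar(affinity_nm) else out


def sigmoid_affinity_transform(value) -> np.ndarray | float:
    """``1 / (1 + exp(x))``, the decreasing logistic transform."""
    out = expit(-np.asarray(value, dtype=float))
    return float(out) if np.isscalar(value) else out


def analyze_cohort(
    patients: list[PatientRecord],
    loads,
    horizon_days: float | None = None,
) -> GroupComparison:
    """Median-split the cohort by load and run survival + biomarker tests."""
    loads = np.asarray(loads, dtype=float)
    if len(loads) != len(patients):
        raise ValueError("loads must align with patients")
    high = median_split(loads)
    ids = np.array([p.patient_id for p in patients])
    comp = GroupComparison(
        high_patients=ids[high].tolist(), low_patients=ids[~high].tolist()
    )
    if high.any() and (~high).any():
        has_surv = [p.survival_time is not None and p.event is not None for p in patients]
        if all(has_surv):
            times = [p.survival_time for p in patients]
            events = [p.event for p in patients]
            comp.logrank_statistic, comp.logrank_p = logrank_test(
                times, events, high, horizon_days=horizon_days
            )
        for name in ("stromal", "immune", "estimate"):
            values = [getattr(p, name) for p in patients]
            if all(v is not None for v in values):
                comp.score_tests[name] = score_comparison(values, high)
    return comp


def read_patient_table(path) -> list[PatientRecord]:
    """Read per-mutation patient rows into per-patient records.

    Expected CSV columns: ``patient_id``, ``alleles`` (semicolon-separated),
    ``protein_seq``, ``mut_pos`` (1-based).  Candidate 9-mers are the windows
    around each mutation; rows of one patient are pooled.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "alleles", "protein_seq", "mut_pos"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: requires columns {sorted(required)}")
    patients: dict[str, PatientRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        windows = nine_mer_windows(str(row["protein_seq"]), int(row["mut_pos"]))
        if pid not in patients:
            patients[pid] = PatientRecord(
                patient_id=pid,
                alleles=[a for a in str(row["alleles"]).split(";") if a],
                candidates=[],
            )
        patients[pid].candidates.extend(windows)
    return list(patients.values())


def read_clinical_table(path, patients: list[PatientRecord]) -> list[PatientRecord]:
    """Attach survival and biomarker columns from a clinical CSV (by patient_id)."""
    df = pd.read_csv(path).set_index("patient_id")
    for p in patients:
        if p.patient_id not in df.index:
            logger.warning("%s: no clinical row; left unannotated", p.patient_id)
            continue
        row = df.loc[p.patient_id]
        p.survival_time = float(row["time_days"])
        p.event = bool(int(row["event"]))
        for name in ("stromal", "immune", "estimate"):
            if name in df.columns:
                setattr(p, name, float(row[name]))
    return patients
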