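"""Synthetic affinity datasets and patient cohorts with planted ground truth.

The generator emulates the study's two data sources at desk scale:

* an IEDB-style quantitative binding table: each synthetic HLA allele gets a
  fixed random pseudo-sequence and a preferred residue at each anchor
  position of the 9-mer (positions 2 and 9, the positions buried in the
  class-I binding groove).  A peptide whose anchors all match its allele's
  preference draws IC50 log-normally around 50 nM (a strong binder), any
  other peptide around 5000 nM; the 500 nM rule then labels the records.
* a patient cohort: alleles, candidate 9-mers, exponential overall survival
  whose hazard is multiplied by a configurable ratio in the *low*-load
  group (high neoantigen load is protective), independent administrative
  censoring, and biomarker scores with a configurable group mean shift.

All randomness flows from one integer seed; the planted rule is returned so
tests can score any stage against the exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BINDING_THRESHOLD_NM
from .neoantigen import PatientRecord

__all__ = ["SynthConfig", "SynthAffinityData", "SynthCohort",
           "generate_affinity_dataset", "generate_cohort"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Study conditions of the synthetic generator.

    Affinity table: ``n_records`` (allele, 9-mer, IC50) rows over
    ``n_alleles`` alleles; ``binder_fraction`` of peptides have their
    anchors planted to match; IC50 noise is log-normal with ``noise_sd``
    decades around 50 nM (match) or 5000 nM (mismatch).

    Cohort: ``n_patients`` patients with ``alleles_per_patient`` alleles and
    ``candidates_per_patient`` candidate 9-mers each (``plant_prob`` chance
    a candidate matches one of the patient's alleles); exponential survival
    with ``baseline_hazard`` per day, multiplied by ``hazard_ratio`` for
    low-load patients; administrative censoring at ``censor_horizon_days``;
    biomarkers normal with the high-load group shifted by
    ``biomarker_shift`` standard deviations.
    """

    n_alleles: int = 10
    pseudo_length: int = 34
    peptide_length: int = 9
    n_records: int = 1000
    anchor_positions: tuple[int, ...] = (2, 9)
    binder_fraction: float = 0.5
    noise_sd: float = 0.3  # log10 scale
    binder_ic50: float = 50.0
    nonbinder_ic50: float = 5000.0
    n_patients: int = 100
    alleles_per_patient: int = 2
    candidates_per_patient: int = 20
    plant_prob: float = 0.25
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    hazard_ratio: float = 3.0
    censor_horizon_days: float = 1825.0
    biomarker_shift: float = 1.0
    biomarker_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_alleles, self.pseudo_length, self.peptide_length,
               self.n_records) < 1:
            raise ValueError("counts and lengths must be >= 1")
        if not 0.0 < self.binder_fraction < 1.0:
            raise ValueError("binder_fraction must be in (0, 1)")
        if any(not 1 <= p <= self.peptide_length for p in self.anchor_positions):
            raise ValueError("anchor positions must lie inside the peptide")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SynthAffinityData:
    """Generated affinity table plus the planted ground truth."""

    records: pd.DataFrame  # allele, peptide, ic50, label, anchor_match
    pseudo_map: dict[str, str]
    anchor_preferences: dict[str, dict[int, str]]
    config: SynthConfig

    def matches_rule(self, allele: str, peptide: str) -> bool:
        prefs = self.anchor_preferences[allele]
        return all(peptide[p - 1] == aa for p, aa in prefs.items())


@dataclass
class SynthCohort:
    patients: list[PatientRecord] = field(default_factory=list)
    truth: pd.DataFrame | None = None  # patient_id, true_load, high_group
    anchor_preferences: dict[str, dict[int, str]] = field(default_factory=dict)
    pseudo_map: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _make_alleles(rng: np.random.Generator, config: SynthConfig):
    pseudo_map = {}
    prefs: dict[str, dict[int, str]] = {}
    for k in range(config.n_alleles):
        name = f"SYN-A*{k + 1:02d}"
        pseudo_map[name] = _random_seq(rng, config.pseudo_length)
        prefs[name] = {
            p: str(rng.choice(list(_AA))) for p in config.anchor_positions
        }
    return pseudo_map, prefs


def generate_affinity_dataset(config: SynthConfig) -> SynthAffinityData:
    """Generate an IEDB-style quantitative table with a planted anchor rule."""
    rng = np.random.default_rng(config.seed)
    pseudo_map, prefs = _make_alleles(rng, config)
    alleles = list(pseudo_map)
    rows = []
    for _ in range(config.n_records):
        allele = alleles[rng.integers(len(alleles))]
        peptide = list(_random_seq(rng, config.peptide_length))
        if rng.random() < config.binder_fraction:
            for p, aa in prefs[allele].items():
                peptide[p - 1] = aa
        peptide = "".join(peptide)
        match = all(peptide[p - 1] == aa for p, aa in prefs[allele].items())
        mu = config.binder_ic50 if match else config.nonbinder_ic50
        ic50 = 10.0 ** (np.log10(mu) + rng.normal(0.0, config.noise_sd))
        rows.append(
            {
                "allele": allele,
                "peptide": peptide,
                "ic50": ic50,
                "label": int(ic50 <= BINDING_THRESHOLD_NM),
                "anchor_match": match,
            }
        )
    return SynthAffinityData(
        records=pd.DataFrame(rows),
        pseudo_map=pseudo_map,
        anchor_preferences=prefs,
        config=config,
    )


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a patient cohort with known loads and group-dependent survival.

    Each candidate is stored as a 9-mer mutated protein (mutation position
    uniform in 1..9, so the candidate is its own unique window).  The true
    load counts (allele, candidate) pairs matching the planted anchor rule;
    the cohort is median-split on true load, and the low group's hazard is
    ``baseline_hazard * hazard_ratio``.
    """
    rng = np.random.default_rng(config.seed)
    pseudo_map, prefs = _make_alleles(rng, config)
    alleles = list(pseudo_map)

    patients: list[PatientRecord] = []
    true_loads = []
    for k in range(config.n_patients):
        own = rng.choice(
            alleles, size=min(config.alleles_per_patient, len(alleles)), replace=False
        ).tolist()
        candidates = []
        for _ in range(config.candidates_per_patient):
            pep = list(_random_seq(rng, 9))
            if rng.random() < config.plant_prob:
                chosen = own[rng.integers(len(own))]
                for p, aa in prefs[chosen].items():
                    pep[p - 1] = aa
            candidates.append("".join(pep))
        load = sum(
            all(pep[p - 1] == aa for p, aa in prefs[a].items())
            for a in own
            for pep in candidates
        )
        true_loads.append(load)
        patients.append(
            PatientRecord(patient_id=f"PT{k + 1:04d}", alleles=own, candidates=candidates)
        )

    true_loads = np.array(true_loads)
    high = true_loads > np.median(true_loads)
    for p, is_high in zip(patients, high):
        hazard = config.baseline_hazard * (1.0 if is_high else config.hazard_ratio)
        t = rng.exponential(1.0 / hazard)
        if t > config.censor_horizon_days:
            p.survival_time, p.event = config.censor_horizon_days, False
        else:
            p.survival_time, p.event = float(t), True
        shift = config.biomarker_shift if is_high else 0.0
        p.stromal = float(rng.normal(shift, config.biomarker_sd))
        p.immune = float(rng.normal(shift, config.biomarker_sd))
        p.estimate = p.stromal + p.immune

    truth = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "true_load": true_loads,
            "high_group": high,
        }
    )
    return SynthCohort(
        patients=patients,
        truth=truth,
        anchor_preferences=prefs,
        pseudo_map=pseudo_map,
    )
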