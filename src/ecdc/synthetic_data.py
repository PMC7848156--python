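"""Synthetic Medicaid-style claims cohort with planted subgroup structure.

The generator emulates the published structure of early-childhood dental
care in a large pediatric Medicaid ACO: five latent utilization subgroups —
early-, mid-, and late-onset of decay, regular preventive care, and zero
utilization — with printed mixture weights (0.5 / 3.0 / 5.8 / 67.7 / 23.0 %
overall; 0.4 / 2.5 / 4.5 / 35.5 / 57.1 % in the urban stratum), per-subgroup
annual dental cost laws calibrated to printed medians and interquartile
ranges, treatment-onset ages centered at 28 / 35 / 44 months, semiannual
preventive visits, and pre-24-month medical profiles (cost, visit counts,
chronic-disease complexity, first dental visit).

Total costs are drawn from log-normal laws whose parameters come from the
printed median and IQR (:func:`lognormal_from_median_iqr`); how a patient's
total is allocated across their visits is a free design choice of the
generator (decay groups put 70% of cost on T+OR days) — the published
statistics constrain only totals.  About 1% of paid amounts are emitted
negated to exercise the clamping rule, and each patient's claims parse
cleanly through :mod:`ecdc.claims_io`.

The planted truth table (patient -> subgroup, onset age) is emitted
alongside the claims so that pipeline recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import claims_io
from .claims_io import DAYS_PER_MONTH
from .clustering import SubgroupLabel

#: Normal quartile spacing: Phi^-1(0.75).
_Z75 = 0.6744897501960817


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a target median and quartiles.

    ``mu = ln(median)`` and ``sigma = ln(q3/q1) / (2 * 0.67449)`` so that the
    distribution's median equals *median* and its quartile ratio equals
    ``q3/q1``.  ``q1 == q3`` degenerates to a point mass (sigma = 0).
    """
    if median <= 0 or q1 <= 0 or q3 <= 0:
        raise ValueError("median and quartiles must be positive")
    if not (q1 <= median <= q3):
        raise ValueError("need q1 <= median <= q3")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


@dataclass
class SubgroupSpec:
    """Planted parameters of one latent subgroup (all costs 2017 USD)."""

    label: SubgroupLabel
    weight: float
    urban_weight: float
    annual_cost_median: float
    annual_cost_iqr: tuple[float, float]
    onset_center_months: int | None = None      # decay groups only
    onset_jitter_months: int = 2
    n_tnor_mean: float = 2.0                    # follow-up treatment visits
    extra_tor_recurrences: int = 0              # early-onset: repeat OR visits
    preventive_interval_months: int = 6
    # pre-24-month profile
    pre24_medical_cost_median: float = 0.0
    pre24_medical_cost_iqr: tuple[float, float] = (0.0, 0.0)
    pre24_medical_visits_median: float = 16.0
    p_complex: float = 0.0
    p_noncomplex: float = 0.25
    p_any_dental: float = 0.0
    first_dental_age_median: float = 16.0


def default_subgroup_specs() -> list[SubgroupSpec]:
    """Default calibration: the published subgroup structure."""
    return [
        SubgroupSpec(SubgroupLabel.EARLY_ONSET, 0.005, 0.004, 9499.2, (7052.0, 11216.0),
                     onset_center_months=28, extra_tor_recurrences=1,
                     pre24_medical_cost_median=7513.0, pre24_medical_cost_iqr=(4527.0, 12546.0),
                     pre24_medical_visits_median=15.0, p_complex=0.312,
                     p_any_dental=0.295, first_dental_age_median=20.0),
        SubgroupSpec(SubgroupLabel.MID_ONSET, 0.030, 0.025, 5240.7, (4367.0, 6006.0),
                     onset_center_months=35,
                     pre24_medical_cost_median=6550.0, pre24_medical_cost_iqr=(3993.0, 11210.0),
                     pre24_medical_visits_median=15.5, p_complex=0.204,
                     p_any_dental=0.305, first_dental_age_median=18.0),
        SubgroupSpec(SubgroupLabel.LATE_ONSET, 0.058, 0.045, 2989.5, (2483.0, 3781.0),
                     onset_center_months=44,
                     pre24_medical_cost_median=6399.0, pre24_medical_cost_iqr=(3957.0, 10763.0),
                     pre24_medical_visits_median=16.0, p_complex=0.218,
                     p_any_dental=0.247, first_dental_age_median=16.0),
        SubgroupSpec(SubgroupLabel.PREVENTIVE, 0.677, 0.355, 190.8, (99.0, 336.0),
                     pre24_medical_cost_median=6491.0, pre24_medical_cost_iqr=(4003.0, 10824.0),
                     pre24_medical_visits_median=16.0, p_complex=0.175,
                     p_any_dental=0.223, first_dental_age_median=16.0),
        SubgroupSpec(SubgroupLabel.ZERO_UTIL, 0.230, 0.571, 0.0, (0.0, 0.0),
                     pre24_medical_cost_median=5744.0, pre24_medical_cost_iqr=(3545.0, 9710.0),
                     pre24_medical_visits_median=17.0, p_complex=0.136,
                     p_any_dental=0.104, first_dental_age_median=14.0),
    ]


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings.

    ``urban_fraction`` defaults to the published urban-stratum share
    (2,250 / 24,223).  Urban patients draw their subgroup from the urban
    mixture; non-urban patients draw from the complement mixture computed so
    that the cohort-wide mixture equals the overall weights.
    """

    n_patients: int = 10_000
    seed: int = 0
    urban_fraction: float = 2250 / 24223
    p_male: float = 0.51
    negative_payment_rate: float = 0.01
    gapped_enrollment_fraction: float = 0.0
    years: tuple[int, int] = (2009, 2017)
    specs: list[SubgroupSpec] = field(default_factory=default_subgroup_specs)

    def __post_init__(self):
        if self.n_patients < 100:
            raise ValueError("n_patients must be >= 100")
        for attr in ("weight", "urban_weight"):
            total = sum(getattr(s, attr) for s in self.specs)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"subgroup {attr}s must sum to 1, got {total}")

    def nonurban_weights(self) -> np.ndarray:
        """Complement mixture so the whole cohort matches the overall weights."""
        f = self.urban_fraction
        w = np.array([s.weight for s in self.specs])
        if f <= 0:
            return w
        if f >= 1:
            return np.array([s.urban_weight for s in self.specs])
        u = np.array([s.urban_weight for s in self.specs])
        comp = (w - f * u) / (1 - f)
        if (comp < 0).any():
            raise ValueError("urban_fraction too large for the overall/urban mixtures")
        return comp / comp.sum()

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["specs"] = [{**asdict(s), "label": s.label.value} for s in self.specs]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        specs = []
        for s in doc.pop("specs"):
            s["label"] = SubgroupLabel(s["label"])
            s["annual_cost_iqr"] = tuple(s["annual_cost_iqr"])
            s["pre24_medical_cost_iqr"] = tuple(s["pre24_medical_cost_iqr"])
            specs.append(SubgroupSpec(**s))
        doc["years"] = tuple(doc["years"])
        return cls(specs=specs, **doc)


# ---------------------------------------------------------------------------
# Sampling helpers

#: Share of a decay patient's window cost allocated per visit class.
COST_ALLOCATION = {"T_OR": 0.70, "T_NOR": 0.25, "PREV": 0.05}

#: Chronic diagnosis codes used by the generator (two distinct body systems
#: for complex patients, one non-progressive system otherwise); they match
#: the default chronic code map of :mod:`ecdc.pre24_validation`.
COMPLEX_DX = ("Q249", "G809")
NONCOMPLEX_DX = ("J459",)


def _day_in_month(month: int, rng: np.random.Generator) -> int:
    """A service-age day that floors back to *month* under the 30.4375-day month."""
    lo = math.ceil(month * DAYS_PER_MONTH)
    hi = math.ceil((month + 1) * DAYS_PER_MONTH) - 1
    return int(rng.integers(lo, hi + 1))


def _draw_lognormal(median: float, iqr: tuple[float, float], rng: np.random.Generator) -> float:
    mu, sigma = lognormal_from_median_iqr(median, *iqr)
    return float(np.exp(mu + sigma * rng.standard_normal()))


def _preventive_schedule(spec: SubgroupSpec, rng: np.random.Generator) -> list[int]:
    interval = spec.preventive_interval_months
    m = 24 + int(rng.integers(0, interval))
    months = []
    while m <= 60:
        months.append(m)
        m += interval + int(rng.integers(-1, 2))
    return months


def sample_patient(spec: SubgroupSpec, rng: np.random.Generator, patient_id: str,
                   urban: bool, config: GeneratorConfig):
    """Sample one patient: record, claim lines, and planted truth.

    Returns ``(PatientRecord, list[tuple], truth_dict)`` where the claim
    tuples follow :data:`ecdc.claims_io.CLAIM_COLUMNS`.
    """
    sex = "M" if rng.random() < config.p_male else "F"
    if rng.random() < config.gapped_enrollment_fraction:
        gap = int(rng.integers(10, 50))
        spans = [(0, gap), (gap + 1, 60)]
    else:
        spans = [(0, 60)]
    record = claims_io.PatientRecord(patient_id, sex, urban, spans)

    birth_year = int(rng.integers(config.years[0], config.years[1] - 4))
    claims: list[tuple] = []

    def emit(month, code, cost, claim_class="DENTAL", dx=(), day=None):
        if day is None:
            day = _day_in_month(month, rng)
        claims.append((patient_id, claim_class, day, code, ";".join(dx),
                       round(cost, 2), birth_year + day // 365))
        return day

    # ---- dental utilization in the 24-60 month window
    onset = None
    if spec.label is not SubgroupLabel.ZERO_UTIL:
        total = 3.0 * _draw_lognormal(spec.annual_cost_median, spec.annual_cost_iqr, rng)
        prev_months = _preventive_schedule(spec, rng)
        if spec.onset_center_months is None:
            per_visit = total / max(len(prev_months), 1)
            for m in prev_months:
                emit(m, "D1120", per_visit)
        else:
            j = spec.onset_jitter_months
            onset = int(spec.onset_center_months + rng.integers(-j, j + 1))
            tor_months = [onset]
            for r in range(spec.extra_tor_recurrences):
                m = onset + 6 * (r + 1) + int(rng.integers(-2, 3))
                if m <= 60:
                    tor_months.append(m)
            tnor_months, m = [], onset
            for _ in range(1 + rng.poisson(spec.n_tnor_mean)):
                m += int(rng.integers(2, 6))
                if m <= 60:
                    tnor_months.append(m)
            share = dict(COST_ALLOCATION)
            if not prev_months:
                share["T_OR"] += share.pop("PREV")
            if not tnor_months:
                share["T_OR"] += share.pop("T_NOR")
            for m in tor_months:
                day_cost = total * share["T_OR"] / len(tor_months)
                day = emit(m, "D2140", 0.6 * day_cost, dx=("K029",))
                emit(m, "D9220", 0.4 * day_cost, day=day)
            for m in tnor_months:
                emit(m, "D2140", total * share.get("T_NOR", 0) / max(len(tnor_months), 1), dx=("K029",))
            for m in prev_months:
                emit(m, "D1120", total * share.get("PREV", 0) / max(len(prev_months), 1))

    # ---- pre-24-month medical profile
    med_total = _draw_lognormal(spec.pre24_medical_cost_median, spec.pre24_medical_cost_iqr, rng)
    n_med = 1 + int(rng.poisson(max(spec.pre24_medical_visits_median - 1, 0)))
    med_months = sorted(int(m) for m in rng.integers(0, 24, size=n_med))
    u = rng.random()
    if u < spec.p_complex:
        chronic = list(COMPLEX_DX)
    elif u < spec.p_complex + spec.p_noncomplex:
        chronic = list(NONCOMPLEX_DX)
    else:
        chronic = []
    for i, m in enumerate(med_months):
        dx = tuple(chronic) if i == 0 else ()
        emit(m, "99213", med_total / n_med, claim_class="MEDICAL", dx=dx)

    # ---- pre-24-month dental exposure
    if rng.random() < spec.p_any_dental:
        m = int(np.clip(round(spec.first_dental_age_median + 3 * rng.standard_normal()), 4, 23))
        emit(m, "D0120", float(rng.uniform(25, 60)))

    truth = {"patient_id": patient_id, "subgroup": spec.label.value,
             "first_tor_age_months": onset if onset is not None else "",
             "urban": int(urban)}
    return record, claims, truth


def generate_cohort(config: GeneratorConfig, outdir=None):
    """Generate the cohort; returns ``(claims, patients, truth)`` DataFrames.

    With *outdir* set, writes ``claims.csv``, ``patients.csv`` and
    ``truth.csv`` (plus the config as ``generator.yaml``); byte-identical
    across runs for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.specs
    urban_w = np.array([s.urban_weight for s in specs])
    nonurban_w = config.nonurban_weights()

    records, rows, truths = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        urban = bool(rng.random() < config.urban_fraction)
        w = urban_w if urban else nonurban_w
        spec = specs[int(rng.choice(len(specs), p=w))]
        rec, claims, truth = sample_patient(spec, rng, pid, urban, config)
        records.append(rec)
        rows.extend(claims)
        truths.append(truth)

    claims = pd.DataFrame(rows, columns=claims_io.CLAIM_COLUMNS)
    # negate ~1% of paid amounts to exercise the clamping rule
    neg = (rng.random(len(claims)) < config.negative_payment_rate) & (claims["paid"] > 0)
    claims.loc[neg, "paid"] *= -1.0
    patients = claims_io.patients_frame(records)
    truth = pd.DataFrame(truths)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        claims_io.write_claims(claims, outdir / "claims.csv")
        claims_io.write_patients(patients, outdir / "patients.csv")
        truth.to_csv(outdir / "truth.csv", index=False, lineterminator="\n")
        config.to_yaml(outdir / "generator.yaml")
    return claims, patients, truth
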