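"""Virtual-population generation for clinical-trial-like cohorts.

Builds a simulated patient population whose demographic marginals (sex ratio,
age, weight, BMI) match printed summary statistics of a reference trial
population, with per-sex heights drawn from general European values (height is
assumed unrelated to the disease).  Weight is *derived* from BMI and height so
that the BMI = weight / height(m)^2 identity holds exactly for every patient;
the weight marginal is then matched by an acceptance/resampling loop.

Comorbidity tags are assigned by independent Bernoulli draws per tag, except
obesity, which is only granted to patients with BMI > 30 kg/m^2.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "Marginal",
    "PopulationSpec",
    "HeightModel",
    "ComorbiditySpec",
    "VirtualPatient",
    "PopulationError",
    "generate_population",
    "assign_comorbidities",
    "validate_population",
    "compare_populations",
    "patients_to_frame",
    "frame_to_patients",
    "load_population_config",
    "write_patients_csv",
    "read_patients_csv",
]

# Truncation bounds chosen to exclude physiologically impossible adults.
AGE_BOUNDS = (18.0, 90.0)
BMI_BOUNDS = (15.0, 60.0)

# Eurostat-style per-sex adult height defaults (cm); configuration values,
# not literature claims.
DEFAULT_MALE_HEIGHT = (177.6, 7.0)
DEFAULT_FEMALE_HEIGHT = (164.6, 6.5)


def reference_trial_spec(n_patients: int = 500) -> "PopulationSpec":
    """Target marginals of the pooled pivotal-trial reference population
    (N=1,020) used as the virtual-trial template: 34.4% female,
    age 45.53 +/- 13.23 y, weight 90.73 +/- 22.71 kg, BMI 30.48 +/- 7.07."""
    return PopulationSpec(
        n_patients=n_patients,
        female_fraction=0.344,
        age=Marginal(45.53, 13.23),
        weight=Marginal(90.73, 22.71),
        bmi=Marginal(30.48, 7.07),
    )


REFERENCE_TRIAL_N = 1020

# Default comorbidity panel.  The type-II diabetes frequency is 4.38%
# (a cohort of 15 diabetic patients needs ceil(15/0.0438) = 343 subjects);
# the remaining frequencies are configuration placeholders for real-world
# prevalence inputs, not literature claims.
def default_comorbidities() -> list["ComorbiditySpec"]:
    return [
        ComorbiditySpec("obesity", 0.45, "bmi_gt_30"),
        ComorbiditySpec("diabetes_t2", 0.0438),
        ComorbiditySpec("hypertension", 0.30),
        ComorbiditySpec("psoriatic_arthritis", 0.20),
        ComorbiditySpec("nafld", 0.15),
        ComorbiditySpec("anxiety", 0.15),
        ComorbiditySpec("depression", 0.10),
    ]


class PopulationError(RuntimeError):
    """Raised when a population spec cannot be realized."""


@dataclass(frozen=True)
class Marginal:
    """A univariate marginal summarized by mean and standard deviation."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"marginal sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class PopulationSpec:
    """Target marginals of the population to generate."""

    n_patients: int
    female_fraction: float
    age: Marginal
    weight: Marginal
    bmi: Marginal

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HeightModel:
    """Per-sex height distributions (cm)."""

    male: Marginal = Marginal(*DEFAULT_MALE_HEIGHT)
    female: Marginal = Marginal(*DEFAULT_FEMALE_HEIGHT)
    source: str = "european-defaults"

    def __post_init__(self) -> None:
        if self.male.mean <= 0 or self.female.mean <= 0:
            raise ValueError("height means must be > 0")


@dataclass(frozen=True)
class ComorbiditySpec:
    """A comorbidity tag with its population frequency and eligibility rule.

    ``eligibility_rule`` is a predicate identifier: ``"none"`` (everyone is
    eligible) or ``"bmi_gt_30"`` (obesity; only patients with BMI > 30).
    """

    name: str
    frequency: float
    eligibility_rule: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")
        if self.eligibility_rule not in ("none", "bmi_gt_30"):
            raise ValueError(f"unknown eligibility rule {self.eligibility_rule!r}")


@dataclass(frozen=True)
class VirtualPatient:
    id: str
    sex: str  # "male" | "female"
    age: float
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2
    comorbidities: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        expected = self.weight / (self.height / 100.0) ** 2
        if not math.isclose(self.bmi, expected, rel_tol=1e-6):
            raise ValueError(
                f"patient {self.id}: bmi {self.bmi} inconsistent with "
                f"weight/height ({expected:.6f})"
            )


def _truncnorm(lo: float, hi: float, loc: float, scale: float):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm(a, b, loc=loc, scale=scale)


def _calibrated_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter such that the [lo, hi]-truncated normal with the
    given scale has mean equal to ``target_mean``.

    Plain truncation shifts the mean away from the printed target (e.g. an age
    marginal truncated at 18 becomes systematically older); calibrating the
    location removes that bias so generated marginals are centered on the
    reference values they are meant to reproduce.
    """
    if sd == 0:
        return target_mean

    def gap(loc: float) -> float:
        return _truncnorm(lo, hi, loc, sd).mean() - target_mean

    lo_b, hi_b = target_mean - 5 * sd, target_mean + 5 * sd
    return optimize.brentq(gap, lo_b, hi_b, xtol=1e-10)


def _draw(marg: Marginal, lo: float, hi: float, n: int, rng, calibrate: bool = True):
    if marg.sd == 0:
        if not lo <= marg.mean <= hi:
            raise PopulationError(
                f"degenerate marginal mean {marg.mean} outside bounds [{lo}, {hi}]"
            )
        return np.full(n, marg.mean)
    loc = _calibrated_loc(marg.mean, marg.sd, lo, hi) if calibrate else marg.mean
    return _truncnorm(lo, hi, loc, marg.sd).rvs(size=n, random_state=rng)


def generate_population(
    spec: PopulationSpec,
    heights: HeightModel | None = None,
    seed: int = 0,
    *,
    max_redraws: int = 10_000,
    accept_se: float = 0.5,
) -> list[VirtualPatient]:
    """Generate ``spec.n_patients`` virtual patients matching the marginals.

    Sex is Bernoulli(female_fraction); age and BMI come from mean-calibrated
    truncated normals; height from the per-sex model; weight is derived as
    bmi * height(m)^2.  The joint sample is redrawn until the weight sample
    mean lies within ``accept_se`` standard errors of the target mean and the
    sample sd within ``accept_se`` standard errors of the target sd
    (SE(sd) ~ sd / sqrt(2n)).
    """
    heights = heights or HeightModel()
    n = spec.n_patients
    if n == 0:
        return []
    rng = np.random.default_rng(seed)

    se_mean = spec.weight.sd / math.sqrt(n)
    se_sd = spec.weight.sd / math.sqrt(2 * n)

    height_lo_hi = {
        "male": (heights.male, heights.male.mean - 4 * heights.male.sd,
                 heights.male.mean + 4 * heights.male.sd),
        "female": (heights.female, heights.female.mean - 4 * heights.female.sd,
                   heights.female.mean + 4 * heights.female.sd),
    }

    # sex is drawn once per seed: resampling it inside the weight-acceptance
    # loop would couple the sex ratio to the weight condition (shorter female
    # patients lower the weight mean) and bias the realized ratio
    female = rng.random(n) < spec.female_fraction

    last_mean_gap = last_sd_gap = math.inf
    for _ in range(max_redraws):
        age = _draw(spec.age, *AGE_BOUNDS, n=n, rng=rng)
        bmi = _draw(spec.bmi, *BMI_BOUNDS, n=n, rng=rng)
        height = np.empty(n)
        for sex_name, mask in (("male", ~female), ("female", female)):
            m = int(mask.sum())
            if m:
                marg, lo, hi = height_lo_hi[sex_name]
                height[mask] = _draw(marg, lo, hi, n=m, rng=rng, calibrate=False)
        weight = bmi * (height / 100.0) ** 2

        last_mean_gap = abs(float(weight.mean()) - spec.weight.mean)
        last_sd_gap = abs(float(weight.std(ddof=1)) - spec.weight.sd) if n > 1 else 0.0
        # tiny epsilon keeps degenerate (sd = 0) marginals acceptable at
        # floating-point round-off
        if (last_mean_gap <= accept_se * se_mean + 1e-9
                and last_sd_gap <= accept_se * se_sd + 1e-9):
            break
    else:
        which = "mean" if last_mean_gap > accept_se * se_mean else "sd"
        raise PopulationError(
            f"could not match weight marginal {which} within "
            f"{accept_se} SE after {max_redraws} redraws"
        )

    width = len(str(n))
    return [
        VirtualPatient(
            id=f"P{i + 1:0{width}d}",
            sex="female" if female[i] else "male",
            age=float(age[i]),
            height=float(height[i]),
            weight=float(weight[i]),
            bmi=float(bmi[i]),
        )
        for i in range(n)
    ]


def assign_comorbidities(
    patients: list[VirtualPatient],
    specs: list[ComorbiditySpec],
    seed: int = 0,
) -> list[VirtualPatient]:
    """Assign comorbidity tags by independent Bernoulli draws.

    Tags with the ``bmi_gt_30`` rule are drawn only among eligible patients,
    with the per-eligible probability inflated so the expected *population*
    frequency equals the requested one; if the requested frequency exceeds the
    eligible fraction this is unrealizable and raises :class:`PopulationError`.
    """
    rng = np.random.default_rng(seed)
    n = len(patients)
    tags: list[set] = [set(p.comorbidities) for p in patients]
    for cspec in specs:
        if cspec.eligibility_rule == "bmi_gt_30":
            eligible = np.array([p.bmi > 30.0 for p in patients])
            n_eligible = int(eligible.sum())
            if cspec.frequency == 0 or n == 0:
                continue
            p_within = cspec.frequency * n / max(n_eligible, 1)
            if n_eligible == 0 or p_within > 1.0:
                raise PopulationError(
                    f"comorbidity {cspec.name!r}: requested frequency "
                    f"{cspec.frequency} exceeds eligible fraction "
                    f"{n_eligible / max(n, 1):.4f}"
                )
            draws = rng.random(n) < p_within
            hit = draws & eligible
        else:
            hit = rng.random(n) < cspec.frequency
        for i in np.flatnonzero(hit):
            tags[i].add(cspec.name)
    return [replace(p, comorbidities=frozenset(t)) for p, t in zip(patients, tags)]


def validate_population(
    patients: list[VirtualPatient],
    spec: PopulationSpec,
    reference_label: str = "reference",
    reference_n: int | None = None,
) -> pd.DataFrame:
    """Compare generated marginals against the reference summary.

    Continuous variables use the unpaired two-tailed t-test against the
    reconstructed reference summary (mean/sd/n); sex uses an exact binomial
    test against the reference proportion.  ``reference_n`` defaults to the
    generated size.
    """
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to validate")
    frame = patients_to_frame(patients)
    n_ref = reference_n or len(patients)
    rows = []
    targets = {
        "age": spec.age,
        "weight_kg": spec.weight,
        "bmi": spec.bmi,
    }
    for var, marg in targets.items():
        x = frame[var].to_numpy()
        m, s = float(x.mean()), float(x.std(ddof=1))
        if s == 0 and marg.sd == 0:
            t_stat, p = float("nan"), float("nan")
        else:
            t_stat, p = stats.ttest_ind_from_stats(
                m, s, len(x), marg.mean, marg.sd, n_ref, equal_var=False
            )
        rows.append(
            {
                "variable": var,
                "generated_mean": m,
                "generated_sd": s,
                "target_mean": marg.mean,
                "target_sd": marg.sd,
                "statistic": float(t_stat),
                "p_value": float(p),
                "test": "t-test" if s or marg.sd else "undefined",
                "reference": reference_label,
            }
        )
    n_female = int((frame["sex"] == "female").sum())
    binom = stats.binomtest(n_female, len(patients), spec.female_fraction)
    rows.append(
        {
            "variable": "female_fraction",
            "generated_mean": n_female / len(patients),
            "generated_sd": float("nan"),
            "target_mean": spec.female_fraction,
            "target_sd": float("nan"),
            "statistic": float(n_female),
            "p_value": float(binom.pvalue),
            "test": "binomial",
            "reference": reference_label,
        }
    )
    return pd.DataFrame(rows)


def compare_populations(
    patients_a: list[VirtualPatient],
    patients_b: list[VirtualPatient],
    variables: tuple = ("age", "height_cm", "weight_kg", "bmi"),
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of two simulated populations (e.g. the
    disease cohort vs a European-like comparator)."""
    fa, fb = patients_to_frame(patients_a), patients_to_frame(patients_b)
    rows = []
    for var in variables:
        res = stats.ranksums(fa[var], fb[var])
        rows.append(
            {
                "variable": var,
                "mean_a": float(fa[var].mean()),
                "mean_b": float(fb[var].mean()),
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "test": "wilcoxon-rank-sum",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = ["id", "sex", "age", "height_cm", "weight_kg", "bmi", "comorbidities"]


def patients_to_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in patients],
            "sex": [p.sex for p in patients],
            "age": [p.age for p in patients],
            "height_cm": [p.height for p in patients],
            "weight_kg": [p.weight for p in patients],
            "bmi": [p.bmi for p in patients],
            "comorbidities": [";".join(sorted(p.comorbidities)) for p in patients],
        }
    )


def frame_to_patients(frame: pd.DataFrame) -> list[VirtualPatient]:
    out = []
    for row in frame.itertuples(index=False):
        tags = frozenset(t for t in str(row.comorbidities).split(";") if t and t != "nan")
        out.append(
            VirtualPatient(
                id=str(row.id),
                sex=str(row.sex),
                age=float(row.age),
                height=float(row.height_cm),
                weight=float(row.weight_kg),
                bmi=float(row.bmi),
                comorbidities=tags,
            )
        )
    return out


def write_patients_csv(patients: list[VirtualPatient], path) -> None:
    patients_to_frame(patients).to_csv(path, index=False, float_format="%.10g")


def read_patients_csv(path) -> list[VirtualPatient]:
    frame = pd.read_csv(path, keep_default_na=False)
    return frame_to_patients(frame)


def load_population_config(path):
    """Read a YAML population spec.

    Expected keys: ``n_patients``, ``female_fraction``, ``age``/``weight``/
    ``bmi`` (each ``{mean, sd}``), optional ``heights`` (``male``/``female``
    ``{mean, sd}``) and ``comorbidities`` (list of ``{name, frequency,
    eligibility_rule}``).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    spec = PopulationSpec(
        n_patients=int(cfg["n_patients"]),
        female_fraction=float(cfg["female_fraction"]),
        age=Marginal(**cfg["age"]),
        weight=Marginal(**cfg["weight"]),
        bmi=Marginal(**cfg["bmi"]),
    )
    if "heights" in cfg:
        heights = HeightModel(
            male=Marginal(**cfg["heights"]["male"]),
            female=Marginal(**cfg["heights"]["female"]),
            source=cfg["heights"].get("source", "config"),
        )
    else:
        heights = HeightModel()
    comorbidities = [
        ComorbiditySpec(
            name=c["name"],
            frequency=float(c["frequency"]),
            eligibility_rule=c.get("eligibility_rule", "none"),
        )
        for c in cfg.get("comorbidities", [])
    ]
    return spec, heights, comorbidities
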