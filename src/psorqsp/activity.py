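"""Synthetic predicted-protein-activity generator.

Stands in for a proprietary network-propagation engine: it emits, per
patient-arm model, a vector of predicted protein activities in [-1, 1]
(-1 fully inhibited, +1 fully activated).  The generative story is

  baseline: each disease-effector protein sits at its pathological sign v_i;
  drug:     exposure pulls every effector toward 0 by an Emax/EC50 (Hill)
            fraction of its baseline;
  groups:   comorbidity-driven mechanistic groups add per-protein offsets,
            creating recoverable cluster structure;
  noise:    additive Gaussian noise, then a smooth tanh squash into [-1, 1].

Everything is deterministic under a seed, so downstream clustering,
scoring and enrichment stages can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinDefinition",
    "MechanisticScenario",
    "ActivityMatrix",
    "exposure_effect",
    "assign_groups",
    "generate_activity",
    "generate_reference_panel",
    "planted_distorter_panel",
    "synthetic_definition",
    "exposure_summary",
]


@dataclass(frozen=True)
class ProteinDefinition:
    """Signed protein effector set defining a condition: entries are
    (protein id, sign) with sign +1 for pathologically activated and -1 for
    pathologically inhibited proteins."""

    entries: tuple  # ((protein_id, sign), ...)
    label: str = ""

    def __post_init__(self) -> None:
        entries = tuple((str(p), int(s)) for p, s in self.entries)
        ids = [p for p, _ in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("protein ids must be unique")
        if any(s not in (-1, 1) for _, s in entries):
            raise ValueError("signs must be -1 or +1")
        object.__setattr__(self, "entries", entries)

    @property
    def ids(self) -> list:
        return [p for p, _ in self.entries]

    @property
    def signs(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    def sign_of(self, protein: str) -> int:
        return dict(self.entries)[protein]

    def subset(self, keep) -> "ProteinDefinition":
        keep = set(keep)
        return ProteinDefinition(
            tuple(e for e in self.entries if e[0] in keep), self.label
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["protein", "sign"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "ProteinDefinition":
        frame = pd.read_csv(path)
        return cls(tuple(zip(frame["protein"], frame["sign"])), label)


@dataclass(frozen=True)
class MechanisticScenario:
    """Parameters of the synthetic activity generator."""

    n_groups: int = 1
    effect_shift: float = 0.0  # group offset magnitude (activity units)
    noise_sd: float = 0.05  # additive noise sd (activity units)
    emax: float = 0.9  # maximal fractional drug effect
    ec50: float = 10.0  # exposure at half-maximal effect, mg/L
    hill: float = 1.0
    group_rule: tuple = ()  # ((comorbidity tag, group index), ...) in priority order
    squash: str = "tanh"  # tanh | clip

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.effect_shift < 0 or self.noise_sd < 0:
            raise ValueError("effect_shift and noise_sd must be >= 0")
        if not 0 < self.emax <= 1:
            raise ValueError("emax must lie in (0, 1]")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be > 0")
        if self.squash not in ("tanh", "clip"):
            raise ValueError("squash must be 'tanh' or 'clip'")
        object.__setattr__(self, "group_rule", tuple(self.group_rule))


@dataclass
class ActivityMatrix:
    """Patient-arm models (rows) x proteins (columns), values in [-1, 1]."""

    values: pd.DataFrame
    arms: pd.Series  # arm label per row, aligned with values.index

    def __post_init__(self) -> None:
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("row and column ids must be unique")
        v = self.values.to_numpy()
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("activities must lie in [-1, 1]")
        self.arms = self.arms.reindex(self.values.index)
        if self.arms.isna().any():
            raise ValueError("every row needs an arm label")

    def to_tsv(self, path, arms_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="model_id",
                           float_format="%.10g")
        if arms_path is not None:
            self.arms.rename("arm").to_frame().to_csv(arms_path, index_label="model_id")

    @classmethod
    def from_tsv(cls, path, arms_path) -> "ActivityMatrix":
        values = pd.read_csv(path, sep="\t", index_col="model_id")
        arms = pd.read_csv(arms_path, index_col="model_id")["arm"]
        return cls(values, arms)


def exposure_effect(conc, emax: float, ec50: float, hill: float = 1.0):
    """Hill exposure-effect link: emax * C^h / (EC50^h + C^h), in [0, emax]."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    ch = conc**hill
    out = emax * ch / (ec50**hill + ch)
    return float(out) if out.ndim == 0 else out


def assign_groups(patients, scenario: MechanisticScenario, seed: int = 0) -> dict:
    """Map patient id -> mechanistic group index.

    If the scenario carries a comorbidity-to-group rule, the first matching
    tag decides; patients matching no rule (or an empty rule) are assigned a
    seeded random group.
    """
    rng = np.random.default_rng(seed)
    groups = {}
    for p in patients:
        g = None
        for tag, idx in scenario.group_rule:
            if tag in p.comorbidities:
                g = idx % scenario.n_groups
                break
        if g is None:
            g = int(rng.integers(scenario.n_groups))
        groups[p.id] = g
    return groups


def _group_offsets(scenario: MechanisticScenario, n_proteins: int, rng) -> np.ndarray:
    """Per-group per-protein mean offsets: magnitude effect_shift with a
    seeded sign pattern in {-1, 0, +1} so groups differ on a random protein
    subset."""
    pattern = rng.integers(-1, 2, size=(scenario.n_groups, n_proteins))
    return scenario.effect_shift * pattern


def generate_activity(
    patients,
    exposures: pd.DataFrame,
    definition: ProteinDefinition,
    scenario: MechanisticScenario,
    seed: int = 0,
    groups: dict | None = None,
) -> ActivityMatrix:
    """Generate the patient-arm x protein activity matrix.

    ``exposures`` needs columns ``patient_id``, ``arm``, ``exposure`` (one row
    per patient-arm model); every patient must appear for every arm listed.
    """
    rng = np.random.default_rng(seed)
    v = definition.signs
    n_prot = len(v)
    offsets = _group_offsets(scenario, n_prot, rng)
    if groups is None:
        groups = assign_groups(patients, scenario, seed=int(rng.integers(2**31)))

    by_patient = {p.id: p for p in patients}
    rows, row_ids, row_arms = [], [], []
    for rec in exposures.itertuples(index=False):
        pid, arm, expo = str(rec.patient_id), str(rec.arm), float(rec.exposure)
        if pid not in by_patient:
            raise KeyError(f"exposure record for unknown patient {pid!r}")
        eff = exposure_effect(expo, scenario.emax, scenario.ec50, scenario.hill)
        base = v * (1.0 - eff)  # drug pulls effectors toward 0
        raw = base + offsets[groups[pid]]
        if scenario.noise_sd > 0:
            raw = raw + rng.normal(0.0, scenario.noise_sd, size=n_prot)
        if scenario.squash == "tanh":
            val = np.tanh(raw)
        else:
            val = np.clip(raw, -1.0, 1.0)
        rows.append(val)
        row_ids.append(f"{pid}_{arm}")
        row_arms.append(arm)
    missing = set(by_patient) - {str(p) for p in exposures["patient_id"]}
    if missing:
        raise KeyError(f"patients without exposure record: {sorted(missing)}")
    values = pd.DataFrame(rows, index=row_ids, columns=definition.ids)
    return ActivityMatrix(values, pd.Series(row_arms, index=row_ids))


def exposure_summary(profile, window: tuple = (84.0, 112.0),
                     metric: str = "mean") -> float:
    """Scalar exposure summary of a concentration profile: mean concentration
    over the steady-state window (default weeks 12-16), or cmax/auc."""
    t, c = profile.times, profile.concentrations
    if metric == "mean":
        mask = (t >= window[0]) & (t <= window[1])
        if not mask.any():
            raise ValueError("window outside the simulated grid")
        return float(c[mask].mean())
    if metric == "cmax":
        return float(c.max())
    if metric == "auc":
        return float(np.trapezoid(c, t))
    raise ValueError(f"unknown exposure metric {metric!r}")


def synthetic_definition(n_proteins: int, seed: int = 0,
                         label: str = "synthetic-psoriasis") -> ProteinDefinition:
    """A synthetic signed effector set with ids PR0001..; stand-in for the
    proprietary disease definition."""
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1, 1], size=n_proteins)
    entries = tuple((f"PR{i + 1:04d}", int(s)) for i, s in enumerate(signs))
    return ProteinDefinition(entries, label)


def generate_reference_panel(
    n_drugs: int,
    exposure_range: tuple = (0.0, 40.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    emax: float = 0.9,
    ec50: float = 10.0,
    hill: float = 1.0,
    placebo_level: float = 0.05,
    max_response: float = 0.90,
):
    """Synthetic reference-drug efficacy panel for exposure-effect
    calibration.

    Each drug gets an exposure over the range; its true molecular signal is
    tSignal_true = 1 - Hill(exposure) and its clinical response is
    PASI75 = A * tSignal_true + B (+ noise), a monotone increasing function
    of exposure anchored at the placebo level for zero exposure.  Returns the
    panel table and the ground-truth parameter dict for recovery tests.
    """
    if n_drugs < 3:
        raise ValueError("need at least 3 drugs")
    rng = np.random.default_rng(seed)
    a = -(max_response - placebo_level) / emax
    b = placebo_level - a
    exposures = np.sort(rng.uniform(*exposure_range, size=n_drugs))
    exposures[0] = exposure_range[0]  # guarantee a placebo-like anchor
    tsig = 1.0 - exposure_effect(exposures, emax, ec50, hill)
    pasi75 = a * tsig + b
    if noise_sd > 0:
        pasi75 = np.clip(pasi75 + rng.normal(0.0, noise_sd, size=n_drugs), 0.0, 1.0)
    panel = pd.DataFrame(
        {
            "drug": [f"drug{i + 1:02d}" for i in range(n_drugs)],
            "exposure": exposures,
            "tsignal_true": tsig,
            "pasi75": pasi75,
        }
    )
    truth = {"A": a, "B": b, "emax": emax, "ec50": ec50, "hill": hill,
             "placebo_level": placebo_level}
    return panel, truth


def planted_distorter_panel(
    n_proteins: int = 124,
    n_distorters: int = 9,
    n_drugs: int = 12,
    seed: int = 0,
):
    """Per-drug activity panel with planted "distorter" proteins.

    The non-distorter proteins all carry the drug's latent molecular signal
    (so their sign-weighted mean reproduces it exactly and correlates
    perfectly with efficacy); distorters carry independent junk.  Returns
    (panel drugs x proteins, efficacy per drug, definition, distorter ids) -
    the planted truth is the oracle for definition-pruning recovery.
    """
    rng = np.random.default_rng(seed)
    definition = synthetic_definition(n_proteins, seed=seed)
    v = definition.signs
    ids = definition.ids
    distorters = sorted(rng.choice(ids, size=n_distorters, replace=False))
    s = rng.uniform(0.2, 1.0, size=n_drugs)  # latent per-drug signal
    efficacy = 0.9 - 0.8 * s  # exactly linear in the latent signal
    if n_distorters > n_drugs - 2:
        raise ValueError("need n_drugs >= n_distorters + 2 for identifiability")
    # distorter junk vectors are drawn mutually orthogonal and orthogonal to
    # the signal (and the constant), so each distorter strictly degrades the
    # tSignal-efficacy correlation and the planted set is exactly recoverable
    raw = np.column_stack([np.ones(n_drugs), s,
                           rng.normal(size=(n_drugs, n_drugs - 2))])
    q, _ = np.linalg.qr(raw)
    junk_basis = q[:, 2:2 + n_distorters].T
    panel = np.empty((n_drugs, n_proteins))
    dist_set = set(distorters)
    j_junk = 0
    for j, pid in enumerate(ids):
        if pid in dist_set:
            # equal-variance junk (sd 0.5) keeps every distorter's harm to
            # the correlation comparable; cap keeps values inside [-1, 1]
            u = junk_basis[j_junk]
            junk = u * (0.5 / u.std())
            peak = np.max(np.abs(junk))
            if peak > 0.98:
                junk *= 0.98 / peak
            panel[:, j] = v[j] * junk
            j_junk += 1
        else:
            panel[:, j] = v[j] * s
    frame = pd.DataFrame(panel, index=[f"drug{i + 1:02d}" for i in range(n_drugs)],
                         columns=ids)
    eff = pd.Series(efficacy, index=frame.index, name="pasi75")
    return frame, eff, definition, list(distorters)
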