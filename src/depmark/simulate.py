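"""Synthetic mouse-study and human-cohort generators.

The mouse generator emulates a chronic-stress / antidepressant design: four
groups of mice (non-stressed control NS-C, stressed control S-C, stressed +
fluoxetine S-FLX, non-stressed + fluoxetine NS-FLX), profiled in whole blood
and two brain regions (dentate gyrus DG, anterior cingulate cortex ACC) on a
log2-intensity microarray scale.  Gene classes are planted with known effect
structure so every downstream stage (contrasts, reversal filtering, SAM, RRHO,
candidate selection) can be scored against ground truth:

* ``stress_only``       - shifted in every stressed mouse, untouched by drug
                          (blood only).
* ``stress_reversal``   - shifted under stress, restored in treatment
                          responders (blood only).
* ``flx_only``          - shifted in every fluoxetine-treated mouse (blood only).
* ``concordant_up/down``- stress-reversal pattern with the same direction in
                          blood, DG and ACC.
* ``discordant_blood_brain`` - stress-reversal pattern with opposite signs in
                          blood versus brain.

The human generator emulates a longitudinal case/control cohort (10 severe
major-depressive-episode patients free of antidepressants at inclusion, 10
matched controls; visits at weeks 0, 2, 8, 30) assayed by duplicate RT-qPCR
with planted trait / state / prediction biomarker genes and Hamilton
Depression Rating Scale (HDRS) trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PlantedTruth
from .errors import ConfigurationError

MOUSE_GROUPS = ("NS-C", "S-C", "S-FLX", "NS-FLX")
TISSUES = ("blood", "DG", "ACC")

#: Reference genes shipped with every simulated human Ct table; CRYL1 sits in
#: the moderately-expressed stratum, SV2A in the weakly-expressed one.
HUMAN_REFERENCE_GENES = {"CRYL1": 24.0, "SV2A": 32.0}

_BASELINE_MEAN_LOG2 = 8.0   # blood probe baseline centre
_BASELINE_SD_LOG2 = 1.5     # probe-to-probe baseline spread


@dataclass
class MouseSimConfig:
    """Study conditions for the simulated mouse experiment.

    Defaults follow the study design: 8 mice per group, a brain/blood mean
    linear-intensity ratio of ~2.5 (within the observed 2-3x band), a 1.0 log2
    planted effect against 0.5 log2 residual noise, and a 5/8 responder
    fraction among stressed-treated animals.
    """

    n_per_group: int = 8
    n_probes_blood: int = 2000
    n_probes_brain: int = 2000
    brain_intensity_factor: float = 2.5
    n_stress_genes: int = 60
    n_reversal_genes: int = 40
    n_flxonly_genes: int = 30
    n_concordant_genes: int = 40
    n_discordant_genes: int = 30
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.5
    responder_fraction: float = 5.0 / 8.0
    outlier_mouse: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_per_group", "n_probes_blood", "n_probes_brain", "n_stress_genes",
            "n_reversal_genes", "n_flxonly_genes", "n_concordant_genes",
            "n_discordant_genes",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_per_group < 2:
            raise ConfigurationError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if not 2.0 <= self.brain_intensity_factor <= 3.0:
            raise ConfigurationError(
                f"brain_intensity_factor must lie in [2, 3], got {self.brain_intensity_factor}"
            )
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigurationError(
                f"responder_fraction must lie in [0, 1], got {self.responder_fraction}"
            )
        planted = (
            self.n_stress_genes + self.n_reversal_genes + self.n_flxonly_genes
            + self.n_concordant_genes + self.n_discordant_genes
        )
        limit = min(self.n_probes_blood, self.n_probes_brain)
        if planted > limit:
            raise ConfigurationError(
                f"planted gene classes sum to {planted} > shared probe universe {limit}"
            )
        if self.n_reversal_genes > 0 and round(self.responder_fraction * self.n_per_group) < 1:
            raise ConfigurationError(
                "responder_fraction x n_per_group rounds to < 1 responder; "
                "reversal genes would be unrecoverable"
            )
        if self.noise_sd_log2 < 0:
            raise ConfigurationError(f"noise_sd_log2 must be >= 0, got {self.noise_sd_log2}")


@dataclass
class HumanSimConfig:
    """Study conditions for the simulated longitudinal human cohort.

    Slopes are on the scale the validation statistics use: a state gene's
    relative-quantity change tracks the concurrent HDRS change with slope
    ``state_slope`` (RQ units per HDRS point); magnitudes default to ~0.1,
    consistent with reported regressions of roughly ten HDRS points per RQ
    unit.  ``ct_noise_sd`` is per-replicate cycle noise; setting it to 0 makes
    the generator fully deterministic on the expression side, so relative
    quantities invert the planted expression exactly.
    """

    n_patients: int = 10
    n_controls: int = 10
    visit_weeks: tuple[int, ...] = (0, 2, 8, 30)
    hdrs_baseline_min: float = 20.0
    trait_offset_log2: float = 1.0
    state_slope: float = -0.1
    prediction_slope: float = -0.1
    ct_noise_sd: float = 0.15
    subject_sd: float = 0.15
    n_trait_genes: int = 3
    n_state_genes: int = 3
    n_prediction_genes: int = 2
    n_null_genes: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ConfigurationError(
                "n_patients and n_controls must be >= 2 (group statistics undefined below)"
            )
        if list(self.visit_weeks) != sorted(set(self.visit_weeks)):
            raise ConfigurationError(f"visit_weeks must be strictly increasing, got {self.visit_weeks}")
        if len(self.visit_weeks) < 2:
            raise ConfigurationError("need at least two visits")
        if not 0 <= self.hdrs_baseline_min <= 52:
            raise ConfigurationError(
                f"hdrs_baseline_min must lie in [0, 52], got {self.hdrs_baseline_min}"
            )
        for name in ("n_trait_genes", "n_state_genes", "n_prediction_genes", "n_null_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.ct_noise_sd < 0 or self.subject_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")


# ---------------------------------------------------------------------------
# mouse study
# ---------------------------------------------------------------------------

def _mouse_design(config: MouseSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-mouse design table: id, group, responder status."""
    rows = []
    i = 0
    for group in MOUSE_GROUPS:
        for _ in range(config.n_per_group):
            i += 1
            rows.append({"mouse": f"m{i:02d}", "group": group})
    design = pd.DataFrame(rows).set_index("mouse")
    status = []
    for mouse, row in design.iterrows():
        if row["group"] == "S-FLX":
            status.append(
                "responder" if rng.random() < config.responder_fraction else "nonresponder"
            )
        elif row["group"] == "S-C":
            status.append("susceptible")
        else:
            status.append("resilient")
    design["status"] = status
    return design


def _assign_gene_classes(config: MouseSimConfig, rng: np.random.Generator) -> pd.Series:
    n_genes = max(config.n_probes_blood, config.n_probes_brain)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    classes = pd.Series("null", index=pd.Index(genes, name="gene"), dtype=object)
    shared = min(config.n_probes_blood, config.n_probes_brain)
    n_up = config.n_concordant_genes // 2
    counts = [
        ("stress_only", config.n_stress_genes),
        ("stress_reversal", config.n_reversal_genes),
        ("flx_only", config.n_flxonly_genes),
        ("concordant_up", n_up),
        ("concordant_down", config.n_concordant_genes - n_up),
        ("discordant_blood_brain", config.n_discordant_genes),
    ]
    # planted genes live in the shared blood/brain universe
    picked = rng.choice(shared, size=sum(c for _, c in counts), replace=False)
    pos = 0
    for label, count in counts:
        classes.iloc[picked[pos:pos + count]] = label
        pos += count
    return classes


def _behavior_table(design: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Weight gain (%), two coat-state scores and nest-building scores.

    Responders' coat-score sum is drawn below the classification cutoff (<= 2),
    nonresponders' and stressed controls' above it; weight gain and nest scores
    follow the stressed-vs-recovered pattern seen behaviourally (stress raises
    weight gain and coat score and suppresses nest building; fluoxetine restores
    responders).
    """
    rows = []
    for mouse, row in design.iterrows():
        group, status = row["group"], row["status"]
        stressed_untreated = group == "S-C" or (group == "S-FLX" and status == "nonresponder")
        if stressed_untreated:
            weight = rng.normal(24.0, 2.5)
            coat_sum = rng.uniform(2.5, 4.0)
            nest = rng.normal(1.0, 0.6)
        elif group == "S-FLX":  # responder
            weight = rng.normal(18.5, 2.5)
            coat_sum = rng.uniform(0.5, 2.0)
            nest = rng.normal(2.8, 0.6)
        else:  # unstressed
            weight = rng.normal(18.0, 2.5)
            coat_sum = rng.uniform(0.0, 1.0)
            nest = rng.normal(3.2, 0.6)
        split = rng.uniform(0.4, 0.6)
        nest5h = rng.uniform(0.5, 1.5)
        rows.append({
            "mouse": mouse,
            "group": group,
            "weight_gain": round(weight, 2),
            "coat1": round(coat_sum * split, 2),
            "coat2": round(coat_sum * (1 - split), 2),
            "nest5h": round(nest5h, 2),
            "nest24h": round(nest5h + max(nest, 0.0), 2),
        })
    return pd.DataFrame(rows)


def _effect_signs(classes: pd.Series, rng: np.random.Generator) -> np.ndarray:
    """One effect direction per gene, shared by all tissues."""
    sign = rng.choice([-1.0, 1.0], size=len(classes))
    cls = classes.to_numpy()
    sign[cls == "concordant_up"] = 1.0
    sign[cls == "concordant_down"] = -1.0
    return sign


def _tissue_matrix(
    config: MouseSimConfig,
    design: pd.DataFrame,
    classes: pd.Series,
    signs: np.ndarray,
    tissue: str,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    n_probes = config.n_probes_blood if tissue == "blood" else config.n_probes_brain
    genes = classes.index[:n_probes]
    mu = _BASELINE_MEAN_LOG2
    if tissue != "blood":
        mu += math.log2(config.brain_intensity_factor)
    baseline = rng.normal(mu, _BASELINE_SD_LOG2, size=n_probes)

    eff = config.effect_size_log2
    sign = signs[:n_probes].copy()
    cls = classes.iloc[:n_probes].to_numpy()
    if tissue != "blood":
        # discordant genes flip direction between blood and brain
        sign[cls == "discordant_blood_brain"] *= -1.0

    mice = design.index.to_numpy()
    group = design["group"].to_numpy()
    status = design["status"].to_numpy()
    stressed_untreated = (group == "S-C") | ((group == "S-FLX") & (status == "nonresponder"))
    stressed_any = (group == "S-C") | (group == "S-FLX")
    flx_treated = (group == "S-FLX") | (group == "NS-FLX")

    shift = np.zeros((n_probes, len(mice)))
    blood_only = tissue == "blood"
    for i, label in enumerate(cls):
        if label == "stress_only" and blood_only:
            shift[i, stressed_any] = eff * sign[i]
        elif label == "stress_reversal" and blood_only:
            shift[i, stressed_untreated] = eff * sign[i]
        elif label == "flx_only" and blood_only:
            shift[i, flx_treated] = eff * sign[i]
        elif label in ("concordant_up", "concordant_down", "discordant_blood_brain"):
            shift[i, stressed_untreated] = eff * sign[i]

    noise = rng.normal(0.0, config.noise_sd_log2, size=shift.shape)
    values = baseline[:, None] + shift + noise
    if config.outlier_mouse:
        # one globally shifted stressed-control sample, mimicking a technical
        # outlier that clustering should flag for exclusion
        sc = np.flatnonzero(group == "S-C")
        if sc.size:
            values[:, sc[0]] += 2.0

    samples = pd.DataFrame(
        {"tissue": tissue, "group": group, "subject": mice},
        index=pd.Index(mice, name="sample"),
    )
    frame = pd.DataFrame(values, index=pd.Index(genes, name="probe"), columns=mice)
    return ExpressionMatrix(values=frame, samples=samples)


def simulate_mouse_study(
    config: MouseSimConfig | None = None,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame, PlantedTruth]:
    """Generate the three tissue matrices, the behavior table and ground truth.

    Returns
    -------
    matrices
        ``{"blood": ..., "DG": ..., "ACC": ...}`` with identical sample sheets
        (same mice, same groups) apart from the tissue column.
    behavior
        One row per mouse with weight gain, two coat scores and nest scores.
    truth
        Planted gene classes and per-mouse status labels.
    """
    config = config or MouseSimConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(7)
    design = _mouse_design(config, np.random.default_rng(keys[0]))
    classes = _assign_gene_classes(config, np.random.default_rng(keys[1]))
    signs = _effect_signs(classes, np.random.default_rng(keys[2]))
    behavior = _behavior_table(design, np.random.default_rng(keys[3]))
    matrices = {
        tissue: _tissue_matrix(config, design, classes, signs, tissue, np.random.default_rng(key))
        for tissue, key in zip(TISSUES, keys[4:7])
    }
    truth = PlantedTruth(gene_classes=classes, mouse_status=design["status"].copy())
    return matrices, behavior, truth


# ---------------------------------------------------------------------------
# human cohort
# ---------------------------------------------------------------------------

def _hdrs_trajectories(config: HumanSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical table: subject, group, visit week, HDRS score.

    Patients start at or above the severe-episode inclusion threshold and
    improve stochastically (heterogeneous response, so week-8 scores span
    remitters to poor responders); controls stay in the healthy range.
    """
    fractions = {0: 1.0, 2: (0.75, 0.10), 8: (0.45, 0.20), 30: (0.30, 0.15)}
    rows = []
    for i in range(config.n_patients):
        subject = f"P{i + 1:02d}"
        baseline = config.hdrs_baseline_min + rng.uniform(0.0, 8.0)
        for week in config.visit_weeks:
            if week == 0:
                score = baseline
            else:
                mu, sd = fractions.get(week, (0.4, 0.2))
                frac = float(np.clip(rng.normal(mu, sd), 0.05, 0.95))
                score = baseline * frac
            rows.append({"subject": subject, "group": "patient",
                         "visit": week, "hdrs": float(round(score))})
    for i in range(config.n_controls):
        subject = f"C{i + 1:02d}"
        for week in config.visit_weeks:
            rows.append({"subject": subject, "group": "control",
                         "visit": week, "hdrs": float(rng.integers(0, 6))})
    return pd.DataFrame(rows)


def _human_gene_panel(config: HumanSimConfig) -> pd.Series:
    labels = (
        ["trait"] * config.n_trait_genes
        + ["state"] * config.n_state_genes
        + ["prediction"] * config.n_prediction_genes
        + ["null"] * config.n_null_genes
    )
    names = [f"GENE{i + 1:02d}" for i in range(len(labels))]
    return pd.Series(labels, index=pd.Index(names, name="gene"), dtype=object)


def simulate_human_cohort(
    config: HumanSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate duplicate Ct values, the clinical table, and planted labels.

    The expression model works directly on the relative-quantity (RQ) scale
    the validation statistics use (RQ = 1 means "control-like"):

    * trait genes: patients carry a constant ``2**trait_offset_log2 - 1``
      additive offset at every visit;
    * state genes: a patient's RQ change from baseline tracks the concurrent
      HDRS change with slope ``state_slope``;
    * prediction genes: the baseline-to-week-2 RQ change tracks the
      baseline-to-week-8 HDRS change with slope ``prediction_slope``.

    Subject-level scatter is additive on the RQ scale for patients (so it
    cancels in visit differences) and centred in log2 space for controls (so
    the control calibrator has geometric-mean RQ exactly 1).  Cycle thresholds
    are then ``Ct = base_g - log2(expression) + noise`` per replicate, with two
    reference genes (CRYL1, SV2A) at planted expression 1.
    """
    config = config or HumanSimConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    k_clin, k_expr, k_ct = root.spawn(3)
    clinical = _hdrs_trajectories(config, np.random.default_rng(k_clin))
    panel = _human_gene_panel(config)

    rng = np.random.default_rng(k_expr)
    visits = list(config.visit_weeks)
    week2 = visits[1]
    week8 = visits[2] if len(visits) > 2 else visits[-1]
    hdrs = clinical.set_index(["subject", "visit"])["hdrs"]

    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    controls = [f"C{i + 1:02d}" for i in range(config.n_controls)]
    trait_offset = 2.0 ** config.trait_offset_log2 - 1.0

    # planted expression on the RQ scale, per (subject, visit, gene)
    expr: dict[tuple[str, int, str], float] = {}
    for gene, label in panel.items():
        # controls: constant in time, centred in log2 so the calibrator
        # geometric mean is exactly 1
        log_off = rng.normal(0.0, config.subject_sd, size=len(controls))
        log_off -= log_off.mean()
        for subject, lo in zip(controls, log_off):
            for week in visits:
                expr[(subject, week, gene)] = float(2.0 ** lo)
        offsets = rng.normal(0.0, config.subject_sd, size=len(patients))
        for subject, off in zip(patients, offsets):
            base = 1.0 + off + (trait_offset if label == "trait" else 0.0)
            h0 = hdrs[(subject, visits[0])]
            for week in visits:
                value = base
                if label == "state":
                    value += config.state_slope * (hdrs[(subject, week)] - h0)
                elif label == "prediction" and week == week2:
                    value += config.prediction_slope * (hdrs[(subject, week8)] - h0)
                expr[(subject, week, gene)] = float(max(value, 0.05))

    # gene-specific assay baselines (cycles); candidates are well expressed
    base_rng = np.random.default_rng(k_ct)
    gene_base = {gene: float(base_rng.uniform(22.0, 30.0)) for gene in panel.index}
    gene_base.update(HUMAN_REFERENCE_GENES)

    rows = []
    group_of = {s: "patient" for s in patients} | {s: "control" for s in controls}
    all_genes = list(panel.index) + list(HUMAN_REFERENCE_GENES)
    for subject in patients + controls:
        for week in visits:
            for gene in all_genes:
                e = expr.get((subject, week, gene), 1.0)
                ct_true = gene_base[gene] - math.log2(e)
                for rep in (1, 2):
                    noise = float(base_rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd else 0.0
                    rows.append({
                        "subject": subject,
                        "group": group_of[subject],
                        "visit": week,
                        "gene": gene,
                        "replicate": rep,
                        "ct": float(np.clip(ct_true + noise, 10.0, 40.0)),
                    })
    ct_table = pd.DataFrame(rows)
    truth = PlantedTruth(human_gene_classes=panel)
    return ct_table, clinical, truth


def config_to_dict(config: MouseSimConfig | HumanSimConfig) -> dict:
    """Serializable view of a config (for manifests)."""
    d = asdict(config)
    if "visit_weeks" in d:
        d["visit_weeks"] = list(d["visit_weeks"])
    return d
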