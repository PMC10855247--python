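"""Synthetic two-group serum-miRNA qPCR cohorts with known ground truth.

The generative model for a target assay i, sample j (on plate b),
replicate r is additive on the Cq (log2) scale::

    Cq_ijr = baseline_i - effect_i * [j is case] + u_j + a_ij
             - k_i * log2(1 + h_j) + p_b + eps_ijr

where ``u_j ~ N(0, sigma_sample)`` is the per-sample RNA-content shift
(shared by every endogenous assay, absent from spike-ins, which are
added in fixed amounts), ``a_ij ~ N(0, sigma_assay_i)`` is per-assay
biological noise, ``h_j ~ LogNormal(0, hemolysis_scale)`` is the latent
hemolysis level, ``k_i`` the assay's erythrocyte sensitivity (positive
for erythrocyte-enriched assays, whose Cq drops as hemolysis rises),
``p_b`` the plate offset and ``eps ~ N(0, sigma_tech)`` duplicate
technical noise.  A positive ``effect_i`` (log2 units) means the assay
is up-regulated in cases, i.e. its Cq is lower by ``effect_i`` cycles.

Cq is capped at ``max_cq`` (no-amplification ceiling); hemoglobin
absorbance at 414 nm is an affine, noisy readout of the same latent h,
so the two hemolysis metrics agree by construction.  Every latent
variable is returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .plate_model import CqTable, validate_assays, validate_samples

__all__ = [
    "AssaySpec",
    "SimulationConfig",
    "SimulatedCohort",
    "default_panel",
    "full_panel",
    "simulate_cohort",
]


@dataclass(frozen=True)
class AssaySpec:
    """One assay of the simulated panel.

    ``group_effect`` is in log2 units (positive = up in cases, i.e. the
    case-group Cq is lower by that many cycles).  ``erythrocyte_coeff``
    is the hemolysis sensitivity in cycles per log2(1 + h); 0 for
    assays unaffected by erythrocyte contamination.  ``sigma_assay`` is
    per-assay biological noise (cycles, SD) on top of the shared
    per-sample shift.  Spike-ins and the interplate calibrator must
    have no disease effect, no hemolysis sensitivity, and no biological
    variation — they report purely technical behavior.
    """

    assay_id: str
    baseline_cq: float
    group_effect: float = 0.0
    erythrocyte_coeff: float = 0.0
    sigma_assay: float = 0.0
    roles: frozenset = frozenset({"target"})

    def __post_init__(self):
        object.__setattr__(self, "roles", frozenset(self.roles))
        if self.sigma_assay < 0:
            raise ValueError("sigma_assay must be >= 0")
        technical = {
            "spike_in_isolation",
            "spike_in_rt",
            "interplate_calibrator",
        }
        if self.roles & technical:
            if self.group_effect or self.erythrocyte_coeff or self.sigma_assay:
                raise ValueError(
                    f"{self.assay_id}: technical-control assays must have zero "
                    "group effect, erythrocyte coefficient and biological noise"
                )

    @property
    def is_technical(self) -> bool:
        return bool(
            self.roles
            & {"spike_in_isolation", "spike_in_rt", "interplate_calibrator"}
        )


def default_panel(n_generic_targets: int = 15) -> list[AssaySpec]:
    """Compact panel mirroring the validation-phase assay mix.

    Twenty endogenous assays — one designed biomarker (+0.41 log2 in
    cases, the log2 of a 1.33 fold change), two designed-stable
    reference candidates, the hemolysis pair, and generic targets with
    assorted baselines/effects — plus the extraction/RT spike-ins and
    the interplate calibrator.
    """
    panel = [
        AssaySpec("miR-30c-5p", 27.0, group_effect=0.41, sigma_assay=0.5,
                  roles=frozenset({"target"})),
        AssaySpec("miR-30e-5p", 26.0, group_effect=0.0, sigma_assay=0.05,
                  roles=frozenset({"target", "reference_candidate"})),
        AssaySpec("miR-15b-5p", 25.0, group_effect=0.0, sigma_assay=0.05,
                  roles=frozenset({"target", "reference_candidate"})),
        AssaySpec("miR-23a-3p", 24.0, group_effect=0.0, sigma_assay=0.2,
                  roles=frozenset({"target", "hemolysis_stable"})),
        AssaySpec("miR-451a", 19.0, group_effect=0.0, erythrocyte_coeff=2.0,
                  sigma_assay=0.3,
                  roles=frozenset({"target", "hemolysis_erythrocyte"})),
    ]
    # generic targets: baselines spread over the panel's dynamic range,
    # a few true positives/negatives, a couple near the detection limit
    rng = np.random.default_rng(20240203)  # fixed: panel design, not data
    baselines = np.linspace(22.0, 34.5, n_generic_targets)
    effects = np.zeros(n_generic_targets)
    effects[0], effects[1], effects[2] = 0.8, -0.6, 0.5
    sds = rng.uniform(0.3, 0.6, n_generic_targets).round(2)
    for i in range(n_generic_targets):
        roles = {"target"}
        if i in (3, 4):  # plausible but noisier reference candidates
            roles.add("reference_candidate")
        panel.append(
            AssaySpec(
                f"miR-sim-{i + 1:02d}",
                float(baselines[i]),
                group_effect=float(effects[i]),
                sigma_assay=float(sds[i]),
                roles=frozenset(roles),
            )
        )
    panel += [
        AssaySpec("UniSp2", 20.0, roles=frozenset({"spike_in_isolation"})),
        AssaySpec("UniSp4", 24.0, roles=frozenset({"spike_in_isolation"})),
        AssaySpec("UniSp5", 28.0, roles=frozenset({"spike_in_isolation"})),
        AssaySpec("UniSp6", 21.0, roles=frozenset({"spike_in_rt"})),
        AssaySpec("UniSp3", 19.0, roles=frozenset({"interplate_calibrator"})),
    ]
    return panel


def full_panel() -> list[AssaySpec]:
    """185-assay serum/plasma-style profiling panel preset.

    Same designed assays as :func:`default_panel` plus generic targets
    up to 180 endogenous assays; baselines span 20-36 cycles so a
    realistic fraction censors at the detection limit.
    """
    panel = default_panel(n_generic_targets=15)
    named = [a for a in panel if not a.assay_id.startswith("miR-sim-")]
    rng = np.random.default_rng(20240204)  # fixed panel design
    extra = []
    n_extra = 185 - len(named) - 15
    baselines = rng.uniform(20.0, 36.0, n_extra)
    sds = rng.uniform(0.2, 0.8, n_extra)
    effects = np.where(rng.random(n_extra) < 0.15,
                       rng.normal(0.0, 0.5, n_extra), 0.0)
    for i in range(n_extra):
        extra.append(
            AssaySpec(
                f"miR-sim-{i + 16:02d}",
                float(baselines[i]),
                group_effect=float(effects[i]),
                sigma_assay=float(sds[i]),
                roles=frozenset({"target"}),
            )
        )
    return panel + extra


@dataclass
class SimulationConfig:
    """Cohort-level parameters; defaults follow the validation cohort
    (72 controls vs 67 cases; ages 31.7 +/- 5.2 vs 37.5 +/- 7.0 years).
    """

    seed: int = 0
    n_control: int = 72
    n_case: int = 67
    assays: list = field(default_factory=default_panel)
    sigma_tech: float = 0.2        # duplicate technical noise SD (cycles)
    sigma_sample: float = 1.0      # per-sample RNA-content shift SD (cycles)
    plate_offsets: object = 0.5    # list of per-plate cycles, or SD for random draw
    n_plates: int = 2
    n_replicates: int = 2
    hemolysis_scale: float = 1.0   # lognormal sigma of latent h
    absorbance_coeffs: tuple = (0.05, 0.15, 0.02)  # intercept, slope, noise SD
    age_control: tuple = (31.7, 5.2)
    age_case: tuple = (37.5, 7.0)
    detection_limit: float = 35.0
    max_cq: float = 40.0

    def __post_init__(self):
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 samples per group")
        for name in ("sigma_tech", "sigma_sample", "hemolysis_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_plates < 1 or self.n_replicates < 1:
            raise ValueError("n_plates and n_replicates must be >= 1")
        self.assays = [
            a if isinstance(a, AssaySpec) else AssaySpec(**a) for a in self.assays
        ]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("absorbance_coeffs", "age_control", "age_case"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("assays") == "full_panel":
            raw["assays"] = full_panel()
        return cls(**raw)


class SimulatedCohort(NamedTuple):
    cq: CqTable
    samples: pd.DataFrame
    assays: pd.DataFrame
    truth: "GroundTruth"


@dataclass
class GroundTruth:
    """Latent variables behind a simulated cohort."""

    sample_effects: pd.DataFrame   # u_j, h_j, group, age per sample
    plate_offsets: pd.Series       # p_b per plate
    assay_effects: pd.DataFrame    # configured effect sizes per assay
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort from the generative model (fully seed-reproducible).

    Samples are assigned to plates in interleaved order so both groups
    appear on every plate; all wells of a sample share its plate, and
    the interplate calibrator is run for every sample, hence present on
    every plate.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.assays
    n = config.n_control + config.n_case

    sample_ids = np.array(
        [f"C{i + 1:03d}" for i in range(config.n_control)]
        + [f"E{i + 1:03d}" for i in range(config.n_case)]
    )
    is_case = np.r_[np.zeros(config.n_control, bool), np.ones(config.n_case, bool)]

    # latent per-sample variables
    u = rng.normal(0.0, config.sigma_sample, n)
    h = rng.lognormal(0.0, config.hemolysis_scale, n) if config.hemolysis_scale > 0 \
        else np.ones(n)
    a0, a1, a_sd = config.absorbance_coeffs
    absorbance = a0 + a1 * h + rng.normal(0.0, a_sd, n)
    absorbance = np.maximum(absorbance, 0.0)
    age = np.where(
        is_case,
        rng.normal(config.age_case[0], config.age_case[1], n),
        rng.normal(config.age_control[0], config.age_control[1], n),
    )
    age = np.clip(age, 18.0, None).round(1)

    plates = np.array([f"P{(j % config.n_plates) + 1}" for j in range(n)])
    if isinstance(config.plate_offsets, (list, tuple, np.ndarray)):
        offsets = np.asarray(config.plate_offsets, float)
        if len(offsets) != config.n_plates:
            raise ValueError("plate_offsets length must equal n_plates")
    else:
        sd = float(config.plate_offsets)
        offsets = rng.normal(0.0, sd, config.n_plates) if sd > 0 else np.zeros(
            config.n_plates
        )
    plate_names = [f"P{b + 1}" for b in range(config.n_plates)]
    offset_of = dict(zip(plate_names, offsets))

    # per-(sample, assay) biological noise, then replicate technical noise
    n_assays = len(specs)
    baseline = np.array([a.baseline_cq for a in specs])
    effect = np.array([a.group_effect for a in specs])
    k = np.array([a.erythrocyte_coeff for a in specs])
    sigma_a = np.array([a.sigma_assay for a in specs])
    endogenous = np.array([not a.is_technical for a in specs])

    mean_ij = (
        baseline[None, :]
        - effect[None, :] * is_case[:, None]
        + np.where(endogenous[None, :], u[:, None], 0.0)
        - k[None, :] * np.log2(1.0 + h)[:, None]
        + np.array([offset_of[p] for p in plates])[:, None]
    )
    bio = rng.normal(0.0, 1.0, (n, n_assays)) * sigma_a[None, :]
    mean_ij = mean_ij + bio

    reps = []
    for r in range(config.n_replicates):
        eps = (
            rng.normal(0.0, config.sigma_tech, (n, n_assays))
            if config.sigma_tech > 0
            else np.zeros((n, n_assays))
        )
        cq_r = np.minimum(mean_ij + eps, config.max_cq)
        reps.append(cq_r)

    rows = []
    assay_ids = [a.assay_id for a in specs]
    for r, cq_r in enumerate(reps, start=1):
        df = pd.DataFrame(cq_r, index=sample_ids, columns=assay_ids)
        long = df.stack().rename("cq").reset_index()
        long.columns = ["sample_id", "assay_id", "cq"]
        long["replicate"] = r
        rows.append(long)
    long = pd.concat(rows, ignore_index=True)
    long["plate_id"] = long["sample_id"].map(dict(zip(sample_ids, plates)))
    table = CqTable(
        long[["sample_id", "assay_id", "plate_id", "replicate", "cq"]],
        detection_limit=config.detection_limit,
    )

    stages = _draw_stages(rng, int(is_case.sum()))
    phases = _draw_phases(rng, int((~is_case).sum()))
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_case, "endometriosis", "control"),
            "age": age,
            "bmi": np.round(rng.normal(23.5, 3.0, n).clip(18.5, 29.9), 1),
            "phase": np.where(is_case, "unknown", "__fill__"),
            "stage": "not_applicable",
            "absorbance_414": np.round(absorbance, 4),
        }
    )
    samples.loc[~is_case, "phase"] = phases
    samples.loc[is_case, "stage"] = stages
    samples = validate_samples(samples)

    assays = pd.DataFrame(
        {
            "assay_id": assay_ids,
            "roles": [";".join(sorted(a.roles)) for a in specs],
        }
    )
    assays = validate_assays(assays)

    truth = GroundTruth(
        sample_effects=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": np.where(is_case, "endometriosis", "control"),
                "u": u,
                "h": h,
                "age": age,
                "absorbance_414": absorbance,
                "plate_id": plates,
            }
        ),
        plate_offsets=pd.Series(offsets, index=plate_names, name="offset"),
        assay_effects=pd.DataFrame(
            {
                "assay_id": assay_ids,
                "baseline_cq": baseline,
                "group_effect": effect,
                "erythrocyte_coeff": k,
                "sigma_assay": sigma_a,
            }
        ),
        config=config,
    )
    return SimulatedCohort(table, samples, assays, truth)


def _draw_stages(rng: np.random.Generator, n_case: int) -> np.ndarray:
    """ASRM stage mix of the validation cohort (mostly III/IV)."""
    return rng.choice(
        ["I", "II", "III", "IV"], size=n_case, p=[0.015, 0.09, 0.283, 0.612]
    )


def _draw_phases(rng: np.random.Generator, n_control: int) -> np.ndarray:
    """Menstrual-phase mix of the control group."""
    return rng.choice(
        ["proliferative", "secretory", "unknown"],
        size=n_control,
        p=[0.681, 0.097, 0.222],
    )
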