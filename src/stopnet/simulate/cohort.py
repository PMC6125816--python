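"""Multi-subject synthetic cohorts with known ground truth.

Each subject receives an age (uniform over the configured range), race
parameters whose means drift linearly with age (Go RT slowing, SSRT
lengthening), a subject-specific realization of the group ground truth
(evoked amplitudes, coupling, coupling modulation), and a motion
severity that grows with age.

Two latent subject factors carry the injected brain-behavior structure:

* ``z_act`` scales the SuccStop-UnsuccStop evoked contrast and lowers
  SSRT (stronger responsivity difference -> faster stopping);
* ``z_mod`` scales the context-dependent coupling modulation and lowers
  SSRT, with the strength of that link increasing linearly with age
  (the age-moderated association).  A third factor ``z_spont`` scales
  context-independent coupling and is unrelated to SSRT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bold import GroundTruthSpec, gaussian_blob_maps, synthesize_bold
from .design import TaskDesign
from .motion import simulate_motion
from .race import RaceParams, StaircaseConfig, simulate_race_behavior

_AGE_MID = 53.0  # midpoint of the 18-88 year range


@dataclass
class BehaviorLink:
    """How latent brain factors and age shape the generative SSRT (ms).

    ``ssrt_ms = base + age_slope*(age-53) - act_weight*z_act
    - (mod_weight + moderation*age_norm)*z_mod + N(0, resid_sd)``
    with ``age_norm = (age-53)/35`` in [-1, 1].
    """

    base_ssrt_ms: float = 170.0
    ssrt_age_slope: float = 1.0
    go_rt_age_slope: float = 2.0
    act_weight: float = 18.0
    mod_weight: float = 18.0
    moderation: float = 18.0
    resid_sd: float = 12.0
    go_rt_subject_sd: float = 30.0
    ssrt_floor_ms: float = 80.0


@dataclass
class SubjectSpec:
    subject_id: str
    age_years: float
    race: RaceParams
    truth: GroundTruthSpec
    motion_severity: float
    seed: int
    latents: dict[str, float]
    ssrt_true_ms: float


@dataclass
class Cohort:
    subjects: list[SubjectSpec]
    group_truth: GroundTruthSpec
    link: BehaviorLink
    meta: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Per-subject summary of generative ground truth."""
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "age_years": [s.age_years for s in self.subjects],
                "ssrt_true_ms": [s.ssrt_true_ms for s in self.subjects],
                "z_act": [s.latents["z_act"] for s in self.subjects],
                "z_mod": [s.latents["z_mod"] for s in self.subjects],
                "z_spont": [s.latents["z_spont"] for s in self.subjects],
                "motion_severity": [s.motion_severity for s in self.subjects],
            }
        )


def default_ground_truth(
    n_components: int = 5,
    grid_shape: tuple[int, int, int] = (12, 12, 10),
    noise_sd: float = 0.15,
    motion_artifact_gain: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> GroundTruthSpec:
    """Desk-scale ground truth: 5 blob components, 3 coupled pairs.

    Components 0 and 2 respond more to successful stops, 1 and 3 to
    unsuccessful stops; component 4 carries no task response (a
    'resting' component).  Coupling modulation is injected on the
    (0,1) and (2,3) pairs.
    """
    maps = gaussian_blob_maps(n_components, grid_shape, seed=seed)
    k = n_components

    def vec(vals):
        out = np.zeros(k)
        out[: min(k, len(vals))] = vals[: min(k, len(vals))]
        return out

    evoked = {
        "correctGo": vec([0.8, 0.5, 0.2, 0.3, 0.0]),
        "correctNoGo": vec([0.5, 0.4, 0.4, 0.2, 0.0]),
        "SuccStop": vec([1.0, 0.6, 0.9, 0.2, 0.0]),
        "UnsuccStop": vec([0.4, 0.9, 0.3, 0.7, 0.0]),
    }
    base = np.zeros((k, k))
    mod = np.zeros((k, k))
    for i, j, c in [(0, 1, 0.5), (2, 3, 0.4), (0, 2, 0.3)]:
        if max(i, j) < k:
            base[i, j] = base[j, i] = c
    for i, j, m in [(0, 1, 0.5), (2, 3, 0.5)]:
        if max(i, j) < k:
            mod[i, j] = mod[j, i] = m
    return GroundTruthSpec(
        spatial_maps=maps,
        evoked_amplitudes=evoked,
        base_coupling=base,
        coupling_modulation=mod,
        noise_sd=noise_sd,
        motion_artifact_gain=motion_artifact_gain,
        grid_shape=grid_shape,
        age_slopes={
            "go_rt_ms_per_year": 2.0,
            "ssrt_ms_per_year": 1.0,
            "base_coupling_per_agenorm": -0.3,
            "coupling_modulation_per_agenorm": -0.3,
            "motion_per_year": 0.01,
        },
    )


def _subject_truth(
    group: GroundTruthSpec, s_act: float, s_mod: float, s_spont: float
) -> GroundTruthSpec:
    evoked = dict(group.evoked_amplitudes)
    succ = np.asarray(evoked["SuccStop"], dtype=float)
    unsucc = np.asarray(evoked["UnsuccStop"], dtype=float)
    contrast = (succ - unsucc) / 2.0
    mean = (succ + unsucc) / 2.0
    evoked = {**evoked, "SuccStop": mean + s_act * contrast, "UnsuccStop": mean - s_act * contrast}
    return replace(
        group,
        evoked_amplitudes=evoked,
        base_coupling=group.base_coupling * s_spont,
        coupling_modulation=group.coupling_modulation * s_mod,
    )


def generate_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (18.0, 88.0),
    truth: GroundTruthSpec | None = None,
    link: BehaviorLink | None = None,
    latent_gain: float = 0.4,
    seed: int = 0,
) -> Cohort:
    """Draw a cohort with age-dependent behavior and brain ground truth.

    ``latent_gain`` converts the unit-variance latent factors into
    relative scalings of the subject's evoked contrast / coupling
    (floored at 0.05 so scalings stay positive).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    truth = truth if truth is not None else default_ground_truth(seed=seed)
    link = link or BehaviorLink()
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    ages = rng.uniform(lo, hi, n_subjects)
    slopes = truth.age_slopes

    subjects = []
    for i in range(n_subjects):
        age = float(ages[i])
        age_norm = (age - _AGE_MID) / 35.0
        z_act, z_mod, z_spont = rng.standard_normal(3)
        s_act = max(0.05, 1.0 + latent_gain * z_act)
        s_mod = max(
            0.05,
            1.0
            + latent_gain * z_mod
            + slopes.get("coupling_modulation_per_agenorm", 0.0) * age_norm,
        )
        s_spont = max(
            0.05,
            1.0
            + latent_gain * z_spont
            + slopes.get("base_coupling_per_agenorm", 0.0) * age_norm,
        )
        ssrt = (
            link.base_ssrt_ms
            + link.ssrt_age_slope * (age - _AGE_MID)
            - link.act_weight * z_act
            - (link.mod_weight + link.moderation * age_norm) * z_mod
            + link.resid_sd * rng.standard_normal()
        )
        ssrt = max(link.ssrt_floor_ms, ssrt)
        go_mu = (
            450.0
            + link.go_rt_age_slope * (age - _AGE_MID)
            + link.go_rt_subject_sd * rng.standard_normal()
        )
        race = RaceParams(go_rt_mu=go_mu, ssrt_mu=ssrt, trigger_failure_p=0.02)
        severity = float(
            np.exp(0.35 * rng.standard_normal())
            * max(0.1, 1.0 + slopes.get("motion_per_year", 0.0) * (age - _AGE_MID))
        )
        subjects.append(
            SubjectSpec(
                subject_id=f"sub-{i + 1:03d}",
                age_years=age,
                race=race,
                truth=_subject_truth(truth, s_act, s_mod, s_spont),
                motion_severity=severity,
                seed=int(rng.integers(0, 2**31 - 1)),
                latents={"z_act": z_act, "z_mod": z_mod, "z_spont": z_spont},
                ssrt_true_ms=float(ssrt),
            )
        )
    return Cohort(
        subjects=subjects,
        group_truth=truth,
        link=link,
        meta={"age_range": age_range, "seed": seed, "latent_gain": latent_gain},
    )


def simulate_subject_dataset(
    subject: SubjectSpec,
    design: TaskDesign,
    staircase: StaircaseConfig | None = None,
) -> dict:
    """Behavior, motion and BOLD data for one subject (seeded from subject.seed)."""
    rng = np.random.default_rng(subject.seed)
    behavior = simulate_race_behavior(
        design, subject.race, staircase, seed=rng.integers(0, 2**31 - 1)
    )
    motion = {
        s: simulate_motion(
            design.n_volumes_per_session,
            severity=subject.motion_severity,
            age=subject.age_years,
            seed=rng.integers(0, 2**31 - 1),
        )
        for s in range(1, design.n_sessions + 1)
    }
    bold = synthesize_bold(
        design, behavior, subject.truth, motion, seed=rng.integers(0, 2**31 - 1)
    )
    return {"behavior": behavior, "motion": motion, "bold": bold}


def cohort_feature_table(
    cohort: Cohort,
    measurement_noise_sd: float = 0.15,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Noisy subject-level measurements of the generative brain features.

    Emulates the output of the activity/connectivity stages at the
    feature level: per-component responsivity contrasts and per-pair
    coupling values, each equal to the subject's ground-truth value plus
    white measurement noise.  The default noise SD matches the sampling
    error of the imaging-stage estimators at the task's series length
    (Fisher-z SE ~0.12-0.16 for the coupling contrast).  Used for
    prediction-stage studies where running the full imaging pipeline
    per subject is unnecessary.
    """
    rng = np.random.default_rng(seed)
    g = cohort.group_truth
    k = g.n_components
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    act_rows, mod_rows, spont_rows = [], [], []
    for s in cohort.subjects:
        succ = np.asarray(s.truth.evoked_amplitudes["SuccStop"], dtype=float)
        unsucc = np.asarray(s.truth.evoked_amplitudes["UnsuccStop"], dtype=float)
        act_rows.append(succ - unsucc + measurement_noise_sd * rng.standard_normal(k))
        mod_rows.append(
            np.array([s.truth.coupling_modulation[i, j] for i, j in pairs])
            + measurement_noise_sd * rng.standard_normal(len(pairs))
        )
        spont_rows.append(
            np.array([s.truth.base_coupling[i, j] for i, j in pairs])
            + measurement_noise_sd * rng.standard_normal(len(pairs))
        )
    idx = [s.subject_id for s in cohort.subjects]
    act = pd.DataFrame(act_rows, index=idx, columns=[f"ic{c:02d}" for c in range(k)])
    pair_names = [f"ic{i:02d}-ic{j:02d}" for i, j in pairs]
    mod = pd.DataFrame(mod_rows, index=idx, columns=pair_names)
    spont = pd.DataFrame(spont_rows, index=idx, columns=pair_names)
    meta = cohort.table().set_index("subject_id")
    return {"activity": act, "cppi": mod, "spontaneous": spont, "subjects": meta}
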