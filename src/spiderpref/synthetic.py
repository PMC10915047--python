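"""Synthetic cohort generator.

Emulates the design of the augmented-reality spider-customization study:
each participant completes 24 trials (12 per instruction, 8 per spider
orientation, hence 4 per instruction x orientation cell), setting three
perceptual features on a 10-level grid.  Statistical structure is tunable:

* condition means per (feature, instruction) -- defaults follow the grand
  averages of the robust (MMPD) summaries reported for the study cohort:
  dangerous spiders hairy / thick / spider-like, harmless spiders hairless
  / slim / butterfly-like;
* trial-level dispersion growing log-linearly with the participant's SPQ
  score (spider-fearful participants answer less consistently);
* an SPQ-dependent drift of the dangerous-hairiness mean that makes the
  hairiness incoherency index rise with spider fear (the generalization
  effect: the more fearful, the less specular the dangerous and harmless
  settings);
* optional polarized participant subgroups (cluster structure) via
  per-(feature, instruction) offsets of the participant-level latent mean;
* an additive orientation effect on dangerous-hairiness trials where the
  spider approaches the participant.

Trial values are drawn as latent mean + normal noise, clipped to [0, 1]
and snapped to the nearest grid point k/9.  Generation is fully
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    FEATURES,
    INSTRUCTIONS,
    ORIENTATIONS,
    CohortTable,
    GRID_LEVELS,
)

__all__ = ["ClusterGroup", "GeneratorConfig", "reference_config", "generate_cohort"]

#: Recruitment and screening figures of the reference study: 56 volunteers,
#: 10 screened out on psychopathology, 1 drop-out, leaving 45 analyzed
#: (33 women, 12 men).
STUDY_RECRUITED = 56
STUDY_SCREEN_EXCLUDED = 10
STUDY_DROPOUTS = 1
STUDY_WOMEN = 33
STUDY_MEN = 12


def analyzed_sample_size(recruited: int = STUDY_RECRUITED,
                         screen_excluded: int = STUDY_SCREEN_EXCLUDED,
                         dropouts: int = STUDY_DROPOUTS) -> int:
    """Number of participants entering analysis after exclusions."""
    return recruited - screen_excluded - dropouts


@dataclass(frozen=True)
class ClusterGroup:
    """A latent participant subgroup.

    ``offsets`` maps (feature, instruction) to an additive shift of the
    participant-level latent mean; features/instructions not listed are
    unshifted.
    """

    weight: float
    offsets: Mapping[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Parameters
    ----------
    n_participants
        Cohort size after exclusions (reference study: 45).
    spq_range
        Inclusive bounds of the uniform integer SPQ draw.  The reference
        cohort spread continuously from 0/30 to 26/30.
    condition_means
        Target mean per (feature, instruction), on [0, 1].
    base_sd
        Trial-level noise SD for a participant with SPQ = 0, in preference
        units.
    participant_sd
        SD of a participant-level scatter around the condition mean at
        SPQ = 0 (between-participant dispersion beyond cluster structure).
    sd_spq_slope
        Per-SPQ-point slope on the log of both dispersion components:
        trial noise base_sd * exp(sd_spq_slope * SPQ) and participant
        scatter participant_sd * exp(sd_spq_slope * SPQ).  Preference
        spread therefore widens with spider fear both within and between
        participants.
    hairiness_incoherency_slope
        Per-SPQ-point drift of the dangerous-hairiness latent mean,
        centered on the midpoint of ``spq_range`` so condition means are
        preserved: more fearful participants accept less hairy "dangerous"
        spiders, raising their hairiness incoherency.
    cluster_spec
        Optional polarized subgroups; weights must sum to 1.
    orientation_effect
        Additive shift of dangerous-hairiness trial values when the spider
        approaches the participant.
    female_fraction
        Fraction of participants labeled female (reference cohort: 33/45).
    seed
        Seed for all randomness.
    """

    n_participants: int = 45
    spq_range: tuple[int, int] = (0, 26)
    condition_means: Mapping[tuple[str, str], float] = field(default_factory=dict)
    base_sd: float = 0.08
    participant_sd: float = 0.05
    sd_spq_slope: float = 0.03
    hairiness_incoherency_slope: float = 0.004
    cluster_spec: Sequence[ClusterGroup] | None = None
    orientation_effect: float = -0.05
    female_fraction: float = STUDY_WOMEN / (STUDY_WOMEN + STUDY_MEN)
    seed: int = 0

    def validated(self) -> "GeneratorConfig":
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        lo, hi = self.spq_range
        if not (0 <= lo <= hi <= 30):
            raise ValueError("spq_range must satisfy 0 <= low <= high <= 30")
        if not self.condition_means:
            raise ValueError("condition_means must be provided (see reference_config)")
        for key, m in self.condition_means.items():
            if key[0] not in FEATURES or key[1] not in INSTRUCTIONS:
                raise ValueError(f"condition_means: unknown condition {key!r}")
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"condition_means[{key!r}] = {m} outside [0, 1]")
        missing = [(f, i) for f in FEATURES for i in INSTRUCTIONS
                   if (f, i) not in self.condition_means]
        if missing:
            raise ValueError(f"condition_means missing condition(s) {missing}")
        if self.base_sd < 0:
            raise ValueError("base_sd must be >= 0")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.cluster_spec is not None:
            w = sum(g.weight for g in self.cluster_spec)
            if not np.isclose(w, 1.0):
                raise ValueError(f"cluster_spec weights sum to {w}, expected 1")
            for g in self.cluster_spec:
                for key in g.offsets:
                    if key[0] not in FEATURES or key[1] not in INSTRUCTIONS:
                        raise ValueError(f"cluster_spec: unknown condition {key!r}")
        return self


#: Grand-average robust (MMPD) preference per condition in the reference
#: study; 0 = hairy / thick / butterfly-like, 1 = hairless / slim /
#: spider-like.
REFERENCE_CONDITION_MEANS: dict[tuple[str, str], float] = {
    ("hairiness", "dangerous"): 0.33,
    ("hairiness", "harmless"): 0.75,
    ("bodyleg", "dangerous"): 0.34,
    ("bodyleg", "harmless"): 0.71,
    ("locomotion", "dangerous"): 0.77,
    ("locomotion", "harmless"): 0.40,
}

# Polarized subgroups mirroring the study's per-panel clusterings: body/leg
# and locomotion preferences split into two groups at opposite extremes,
# with specular dangerous/harmless settings (offsets mirrored across the
# instructions, so subgroup membership leaves the incoherency index
# untouched); hairiness -- the feature with the smallest between-cluster
# differences -- is left unimodal so its incoherency drift stays the sole
# SPQ-linked hairiness signal.
_REFERENCE_CLUSTER_OFFSETS: dict[tuple[str, str], float] = {
    ("bodyleg", "dangerous"): -0.20,
    ("bodyleg", "harmless"): +0.20,
    ("locomotion", "dangerous"): +0.15,
    ("locomotion", "harmless"): -0.15,
}


def reference_config(seed: int = 0) -> GeneratorConfig:
    """Default configuration reproducing the study's qualitative structure.

    45 participants, SPQ uniform on 0..26, condition means from the robust
    grand averages (dangerous: hairy/thick/spider-like; harmless:
    hairless/slim/butterfly-like), SPQ-dependent dispersion and hairiness
    incoherency, and two equal-weight polarized subgroups on body/leg and
    locomotion.
    """
    mirrored = {k: -v for k, v in _REFERENCE_CLUSTER_OFFSETS.items()}
    return GeneratorConfig(
        n_participants=45,
        condition_means=dict(REFERENCE_CONDITION_MEANS),
        cluster_spec=(
            ClusterGroup(weight=0.5, offsets=_REFERENCE_CLUSTER_OFFSETS),
            ClusterGroup(weight=0.5, offsets=mirrored),
        ),
        seed=seed,
    ).validated()


def _trial_design(rng: np.random.Generator) -> pd.DataFrame:
    """One participant's 24-trial layout in pseudo-randomized order."""
    cells = [(i, o) for i in INSTRUCTIONS for o in ORIENTATIONS for _ in range(4)]
    order = rng.permutation(len(cells))
    rows = [cells[j] for j in order]
    return pd.DataFrame(rows, columns=["instruction", "orientation"])


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a full synthetic cohort under ``config``.

    Deterministic given ``config.seed``.  Every trial value lies on the
    grid {k/9 : k = 0..9}; every participant follows the exact 12/12
    instruction and 8/8/8 orientation bookkeeping.
    """
    cfg = config.validated()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    width = max(2, len(str(n)))
    pids = [f"P{j + 1:0{width}d}" for j in range(n)]

    lo, hi = cfg.spq_range
    spq = rng.integers(lo, hi + 1, size=n)
    spq_center = (lo + hi) / 2.0

    n_female = int(round(n * cfg.female_fraction))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)
    age = np.clip(np.rint(rng.normal(26.2, 5.5, size=n)), 18, 60).astype(int)

    if cfg.cluster_spec is not None:
        # balanced assignment: group sizes follow the weights exactly
        # (largest-remainder rounding), then a random permutation
        weights = np.array([g.weight for g in cfg.cluster_spec], dtype=float)
        weights = weights / weights.sum()
        counts = np.floor(weights * n).astype(int)
        remainder = weights * n - counts
        for idx in np.argsort(-remainder)[: n - counts.sum()]:
            counts[idx] += 1
        groups = np.repeat(np.arange(len(counts)), counts)
        rng.shuffle(groups)
    else:
        groups = np.zeros(n, dtype=int)

    p_rows = []
    t_rows = []
    for j, pid in enumerate(pids):
        s = int(spq[j])
        p_rows.append({"participant_id": pid, "spq": s, "included": True,
                       "age": int(age[j]), "sex": sex[j]})

        disp = np.exp(cfg.sd_spq_slope * s)
        scatter = rng.normal(0.0, cfg.participant_sd * disp,
                             size=(len(FEATURES), len(INSTRUCTIONS)))
        latent = {}
        for fi, f in enumerate(FEATURES):
            for ii, instr in enumerate(INSTRUCTIONS):
                m = cfg.condition_means[(f, instr)] + scatter[fi, ii]
                if cfg.cluster_spec is not None:
                    m += cfg.cluster_spec[groups[j]].offsets.get((f, instr), 0.0)
                if f == "hairiness" and instr == "dangerous":
                    m += cfg.hairiness_incoherency_slope * (s - spq_center)
                latent[(f, instr)] = m

        sd = cfg.base_sd * disp
        design = _trial_design(rng)
        noise = rng.normal(0.0, 1.0, size=(len(design), len(FEATURES)))
        for t, (instr, orient) in enumerate(zip(design["instruction"],
                                                design["orientation"])):
            row = {"participant_id": pid, "trial_index": t + 1,
                   "instruction": instr, "orientation": orient}
            for k, f in enumerate(FEATURES):
                v = latent[(f, instr)]
                if f == "hairiness" and instr == "dangerous" and orient == "approaching":
                    v += cfg.orientation_effect
                v = v + sd * noise[t, k]
                v = min(max(v, 0.0), 1.0)
                row[f] = np.rint(v * (GRID_LEVELS - 1)) / (GRID_LEVELS - 1)
            t_rows.append(row)

    participants = pd.DataFrame(p_rows)
    trials = pd.DataFrame(t_rows)
    return CohortTable(participants=participants, trials=trials)
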