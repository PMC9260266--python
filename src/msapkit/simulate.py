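"""Synthetic MSAP experiment generator with known ground truth.

The generator emulates a 5-azacytidine dose–response design on CCGG loci:

1. Each locus gets a control methylation state drawn from ``state_probs``
   over {UNMETHYLATED, HEMI, INTERNAL_FULL, HYPER}.
2. Each dose demethylates each locus by at most ONE step with probability
   ``p(d) = 1 - exp(-kappa * d)`` (5-azaC passively strips methylation, with
   a smooth saturating dose response):  HYPER -> HEMI or INTERNAL_FULL
   (equal odds), INTERNAL_FULL -> UNMETHYLATED, HEMI -> UNMETHYLATED.
   Independently, a locus whose demethylation event did not fire may gain one
   step with probability ``gain_prob`` (UNMETHYLATED -> HEMI or INTERNAL_FULL
   equal odds, HEMI -> HYPER), producing the rare methylation-gain (B-type)
   transitions seen in real dose studies.
3. Each state renders deterministically into the H/M band pair of its MSAP
   pattern; per replicate, each band flag is flipped independently with
   probability ``call_error`` (scoring noise on gels).

All randomness derives from a single seed through ``numpy``
``SeedSequence`` spawning, so every artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .io import BandMatrix, MsapValidationError, SampleMeta

__all__ = [
    "MethylationState",
    "SimulationConfig",
    "SimulatedExperiment",
    "render_bands",
    "apply_dose",
    "simulate_experiment",
    "one_step_kernel",
    "estimate_kappa",
    "STATE_TO_PATTERN",
]


class MethylationState(str, Enum):
    """Ground-truth CCGG methylation states."""

    UNMETHYLATED = "UNMETHYLATED"
    HEMI = "HEMI"
    INTERNAL_FULL = "INTERNAL_FULL"
    HYPER = "HYPER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed order used for integer coding and kernel rows/columns.
STATE_ORDER = (
    MethylationState.UNMETHYLATED,
    MethylationState.HEMI,
    MethylationState.INTERNAL_FULL,
    MethylationState.HYPER,
)
_STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}

#: MSAP pattern label each state renders as (zero band-call noise).
STATE_TO_PATTERN = {
    MethylationState.UNMETHYLATED: "I",
    MethylationState.HEMI: "II",
    MethylationState.INTERNAL_FULL: "III",
    MethylationState.HYPER: "IV",
}

_RENDER = {
    MethylationState.UNMETHYLATED: (1, 1),
    MethylationState.HEMI: (1, 0),
    MethylationState.INTERNAL_FULL: (0, 1),
    MethylationState.HYPER: (0, 0),
}


def render_bands(state: MethylationState) -> tuple[int, int]:
    """Deterministic (h, m) band pair of a methylation state."""
    return _RENDER[MethylationState(state)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dose–response experiment.

    Defaults mirror a typical plant MSAP dose study: a few hundred scorable
    loci, three replicates, doses 0/15/50/100 μM, a mostly-unmethylated
    control genome with hemi-methylation the commonest methylated state, a
    demethylation rate constant giving a clearly dose-dependent but
    unsaturated response over 15–100 μM, rare methylation gains, and a small
    per-band miscall probability.
    """

    n_loci: int = 500
    state_probs: tuple = (0.45, 0.25, 0.15, 0.15)  # U, HEMI, FULL, HYPER
    doses: tuple = (0.0, 15.0, 50.0, 100.0)
    kappa: float = 0.007  # per-μM demethylation rate constant
    gain_prob: float = 0.01
    call_error: float = 0.02
    n_replicates: int = 3
    tissue: str = "root"
    stage: str = "M"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise MsapValidationError("n_loci must be >= 1")
        probs = np.asarray(self.state_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-12:
            raise MsapValidationError(
                "state_probs must be 4 non-negative numbers summing to 1"
            )
        if self.kappa < 0:
            raise MsapValidationError("kappa must be >= 0")
        if not 0.0 <= self.gain_prob < 1.0:
            raise MsapValidationError("gain_prob must be in [0, 1)")
        if not 0.0 <= self.call_error < 0.5:
            raise MsapValidationError("call_error must be in [0, 0.5)")
        if self.n_replicates < 1:
            raise MsapValidationError("n_replicates must be >= 1")
        if any(d < 0 for d in self.doses):
            raise MsapValidationError("doses must be >= 0")


def demethylation_prob(dose: float, kappa: float) -> float:
    """p(d) = 1 - exp(-kappa * d), the per-locus one-step probability."""
    return 1.0 - float(np.exp(-kappa * float(dose)))


def one_step_kernel(p: float, g: float) -> np.ndarray:
    """Analytic 4x4 state-transition matrix of one treatment step.

    Rows/columns follow ``STATE_ORDER`` (U, HEMI, FULL, HYPER); ``p`` is the
    demethylation probability, ``g`` the gain probability.  Demethylation
    takes precedence on HEMI loci, where both events could apply.
    """
    return np.array(
        [
            [1 - g, g / 2, g / 2, 0.0],
            [p, (1 - p) * (1 - g), 0.0, (1 - p) * g],
            [p, 0.0, 1 - p, 0.0],
            [0.0, p / 2, p / 2, 1 - p],
        ]
    )


def apply_dose(
    states: np.ndarray,
    dose: float,
    kappa: float,
    gain_prob: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Apply one treatment step to an integer-coded state vector.

    ``states`` is an array of indices into ``STATE_ORDER``.  Each locus
    demethylates one step with probability ``1 - exp(-kappa * dose)``;
    independently drawn gain events (probability ``gain_prob``) apply only
    where the demethylation event did not fire.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    states = np.asarray(states, dtype=np.int64)
    p = demethylation_prob(dose, kappa)
    demeth = rng.random(states.size) < p
    gain = rng.random(states.size) < gain_prob
    coin = rng.random(states.size) < 0.5  # equal-odds branch chooser

    u, h, f, y = 0, 1, 2, 3
    out = states.copy()
    # demethylation one step (no-op on U)
    fired = demeth & (states != u)
    out[fired & (states == h)] = u
    out[fired & (states == f)] = u
    hy = fired & (states == y)
    out[hy & coin] = h
    out[hy & ~coin] = f
    # gain one step where demethylation did not fire
    gained = gain & ~fired
    gu = gained & (states == u)
    out[gu & coin] = h
    out[gu & ~coin] = f
    out[gained & (states == h)] = y
    return out


@dataclass
class SimulatedExperiment:
    """Output bundle of :func:`simulate_experiment`."""

    config: SimulationConfig
    matrices: dict  # dose -> BandMatrix (n_replicates samples)
    truth: pd.DataFrame  # locus x dose ground-truth state labels

    def matrix(self, dose: float) -> BandMatrix:
        return self.matrices[float(dose)]


def _dose_label(dose: float) -> str:
    return str(int(dose)) if float(dose).is_integer() else str(dose)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Simulate control + treated band matrices with ground truth.

    Deterministic given ``config.seed``.  Control states are drawn once per
    locus; each positive dose applies one treatment step to the control
    states (doses are independent arms of one experiment, not a time
    course).  Replicates share the arm's true states and differ only in
    band-call noise.
    """
    root_ss = np.random.SeedSequence(config.seed)
    ss_states, ss_dose, ss_noise = root_ss.spawn(3)
    rng_states = np.random.default_rng(ss_states)

    n = config.n_loci
    loci = [f"L{i + 1:05d}" for i in range(n)]
    probs = np.asarray(config.state_probs, dtype=float)
    control = rng_states.choice(4, size=n, p=probs)

    dose_rngs = {
        float(d): np.random.default_rng(s)
        for d, s in zip(config.doses, ss_dose.spawn(len(config.doses)))
    }
    noise_rngs = {
        float(d): np.random.default_rng(s)
        for d, s in zip(config.doses, ss_noise.spawn(len(config.doses)))
    }

    truth_cols = {}
    matrices = {}
    idx = pd.Index(loci, name="locus_id")
    for dose in (float(d) for d in config.doses):
        if dose == 0.0:
            states = control.copy()
        else:
            states = apply_dose(
                control, dose, config.kappa, config.gain_prob, rng=dose_rngs[dose]
            )
        truth_cols[f"state_{_dose_label(dose)}uM"] = [
            STATE_ORDER[s].value for s in states
        ]
        h_true = np.array([_RENDER[STATE_ORDER[s]][0] for s in states])
        m_true = np.array([_RENDER[STATE_ORDER[s]][1] for s in states])

        samples, h_cols, m_cols = [], {}, {}
        nrng = noise_rngs[dose]
        for rep in range(1, config.n_replicates + 1):
            sid = f"{config.tissue}_{config.stage}_{_dose_label(dose)}uM_r{rep}"
            samples.append(
                SampleMeta(sid, config.tissue, config.stage, dose, rep)
            )
            if config.call_error > 0:
                flip_h = nrng.random(n) < config.call_error
                flip_m = nrng.random(n) < config.call_error
                h_cols[sid] = np.where(flip_h, 1 - h_true, h_true)
                m_cols[sid] = np.where(flip_m, 1 - m_true, m_true)
            else:
                h_cols[sid] = h_true.copy()
                m_cols[sid] = m_true.copy()
        matrices[dose] = BandMatrix(
            samples=samples,
            h=pd.DataFrame(h_cols, index=idx, dtype="Int64"),
            m=pd.DataFrame(m_cols, index=idx, dtype="Int64"),
        )
    truth = pd.DataFrame(truth_cols, index=idx)
    return SimulatedExperiment(config=config, matrices=matrices, truth=truth)


def estimate_kappa(
    control_states: np.ndarray | list,
    treated_states: np.ndarray | list,
    dose: float,
) -> float:
    """Invert the dose response to recover the rate constant kappa.

    Among loci that were demethylatable in the control (not UNMETHYLATED),
    the fraction whose state changed by the demethylation move estimates
    ``p = 1 - exp(-kappa * dose)``; assumes gain events are negligible.
    """
    if dose <= 0:
        raise MsapValidationError("kappa can only be estimated at a positive dose")
    ctrl = np.asarray(_coerce_states(control_states))
    trt = np.asarray(_coerce_states(treated_states))
    if ctrl.shape != trt.shape:
        raise MsapValidationError("state vectors must have equal length")
    eligible = ctrl != 0
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise MsapValidationError("no demethylatable loci in control")
    moved = int((ctrl[eligible] != trt[eligible]).sum())
    p_hat = moved / n_eligible
    if p_hat >= 1.0:
        raise MsapValidationError("all eligible loci moved; kappa not identifiable")
    return float(-np.log(1.0 - p_hat) / dose)


def _coerce_states(states) -> np.ndarray:
    arr = np.asarray(states)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.array([_STATE_INDEX[MethylationState(s)] for s in arr], dtype=np.int64)
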