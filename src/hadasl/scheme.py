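"""Hadamard time-encoded pCASL labeling schemes.

A time-encoded (Hadamard) pCASL acquisition splits the labeling train into
``n_blocks`` sub-boli.  Across ``n_blocks + 1`` acquisitions each sub-bolus is
played either as label or control following the columns of a pruned Sylvester
Hadamard matrix; a linear decode then recovers one perfusion-weighted image
per sub-bolus, each with its own *effective* post-labeling delay (PLD).

This module constructs such schemes: the sign matrix, the effective-PLD
arithmetic, T1-compensated block durations (longer early blocks so every
sub-bolus delivers equal signal at readout despite T1 decay of the label),
and background-suppression (BS) inversion-pulse timing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.linalg import hadamard
from scipy.optimize import minimize

__all__ = [
    "EncodingScheme",
    "BackgroundSuppressionPlan",
    "build_hadamard_matrix",
    "effective_plds",
    "design_t1_compensated_durations",
    "delivered_signal_weights",
    "simulate_mz",
    "optimize_background_suppression",
    "REFERENCE_BLOCK_DURATIONS_S",
    "REFERENCE_BASE_PLD_S",
]

#: Block durations (seconds, play order: longest/first-played first) of the
#: seven-block reference scheme, and its base PLD.
REFERENCE_BLOCK_DURATIONS_S = (1.175, 0.683, 0.482, 0.374, 0.305, 0.257, 0.224)
REFERENCE_BASE_PLD_S = 0.5

#: Default longitudinal relaxation time of arterial blood at 3 T (s).
DEFAULT_T1_BLOOD_S = 1.65


def build_hadamard_matrix(n_blocks: int) -> np.ndarray:
    """Sign matrix of a pruned Sylvester Hadamard design.

    Returns the Sylvester Hadamard matrix of order ``n_blocks + 1`` with its
    all-ones column removed: shape ``(n_blocks + 1, n_blocks)``, entries in
    {+1, -1}.  Rows index encoded acquisitions, columns index sub-boli
    (+1 = label state, -1 = control state).  Columns are mutually orthogonal
    and each sums to zero, which is what makes static tissue cancel in the
    decode.
    """
    order = n_blocks + 1
    if order < 2 or order & (order - 1) != 0:
        raise ValueError(
            f"n_blocks={n_blocks} requires a Hadamard matrix of order "
            f"{order}; Sylvester doubling only constructs orders 2, 4, 8, 16, "
            "... (powers of two), i.e. n_blocks in {1, 3, 7, 15, ...}"
        )
    h = hadamard(order)
    # Sylvester's first column is the all-ones column; drop it.
    return h[:, 1:].astype(np.int8)


def effective_plds(base_pld: float, block_durations) -> np.ndarray:
    """Effective post-labeling delay of each sub-bolus, in play order.

    The label of block ``i`` waits through every later-played block plus the
    base PLD before readout, so its effective PLD is ``base_pld`` plus the
    summed durations of all blocks played after it.  The last-played block
    sees exactly ``base_pld``.
    """
    tau = np.asarray(block_durations, dtype=float)
    if tau.size == 0:
        raise ValueError("block_durations must not be empty")
    if not np.all(np.isfinite(tau)) or np.any(tau <= 0):
        raise ValueError("block_durations must be positive and finite")
    # downstream sum for block i = total after i
    downstream = np.concatenate([np.cumsum(tau[::-1])[-2::-1], [0.0]])
    return base_pld + downstream


def delivered_signal_weights(base_pld: float, block_durations, t1_blood: float) -> np.ndarray:
    """Relative label delivered at readout by each sub-bolus.

    ``w_i = (1 - exp(-tau_i/T1b)) * exp(-PLD_i/T1b)``: label accrued over the
    block duration, decayed in blood over the effective PLD.  A perfectly
    T1-compensated scheme makes these equal across blocks.
    """
    tau = np.asarray(block_durations, dtype=float)
    pld = effective_plds(base_pld, tau)
    if np.isinf(t1_blood):
        return np.zeros_like(tau)
    return -np.expm1(-tau / t1_blood) * np.exp(-pld / t1_blood)


def _solve_equal_weight_train(c: float, base_pld: float, n_blocks: int,
                              t1_blood: float, anchor: float | None) -> np.ndarray:
    """Outward solve of ``(1 - exp(-tau/T1b)) exp(-PLD/T1b) = c`` per block.

    Starts at the readout end; ``anchor`` (if given) fixes the last-played
    duration, otherwise it too is solved from ``c``.  Raises if a block would
    need a delivered-signal level >= 1 (unreachable by any finite duration).
    """
    durations: list[float] = []  # reverse play order (last-played first)
    pld = base_pld
    for k in range(n_blocks):
        if k == 0 and anchor is not None:
            durations.append(float(anchor))
        else:
            level = c * np.exp(pld / t1_blood)
            if level >= 1.0:
                raise ValueError(
                    f"block {n_blocks - k} (play order) needs delivered-signal "
                    f"level {level:.3f} >= 1, unreachable by any finite "
                    "duration; shorten the train, lengthen T1, or lower the "
                    "target level"
                )
            durations.append(float(-t1_blood * np.log1p(-level)))
        pld += durations[-1]
    return np.array(durations[::-1])


def design_t1_compensated_durations(
    base_pld: float,
    n_blocks: int,
    t1_blood: float = DEFAULT_T1_BLOOD_S,
    anchor_duration: float | None = 0.224,
    total_duration: float | None = None,
) -> np.ndarray:
    """Solve block durations so every sub-bolus delivers equal signal.

    Works outward from the readout: the common delivered-signal level ``C``
    is fixed either by the last-played anchor block (duration
    ``anchor_duration`` at PLD ``base_pld``) or, if ``total_duration`` is
    given instead, by requiring the labeling train to sum to that length
    (``C`` found by bisection).  Each block then satisfies
    ``(1 - exp(-tau/T1b)) * exp(-PLD/T1b) = C`` with its effective PLD
    accumulated from the already-solved later blocks, so delivered-signal
    weights are equal for every block by construction.  Returned in play
    order (longest first).

    In the ``t1_blood -> inf`` limit there is no decay to compensate and all
    blocks equal the anchor (or ``total_duration / n_blocks``).
    """
    if t1_blood <= 0:
        raise ValueError("t1_blood must be positive (np.inf allowed)")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if (anchor_duration is None) == (total_duration is None):
        raise ValueError("give exactly one of anchor_duration, total_duration")

    if total_duration is not None:
        if total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if np.isinf(t1_blood):
            return np.full(n_blocks, total_duration / n_blocks)

        def excess(c):
            try:
                return _solve_equal_weight_train(
                    c, base_pld, n_blocks, t1_blood, None
                ).sum() - total_duration
            except ValueError:  # level >= 1 somewhere: effectively infinite
                return np.inf

        # train length grows monotonically with the common level c (jumping
        # to +inf once infeasible), so plain bisection on the sign suffices
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if excess(mid) < 0:
                lo = mid
            else:
                hi = mid
        return _solve_equal_weight_train(lo, base_pld, n_blocks, t1_blood, None)

    if anchor_duration <= 0:
        raise ValueError("anchor_duration must be positive")
    if np.isinf(t1_blood):
        return np.full(n_blocks, float(anchor_duration))
    c = -np.expm1(-anchor_duration / t1_blood) * np.exp(-base_pld / t1_blood)
    return _solve_equal_weight_train(c, base_pld, n_blocks, t1_blood,
                                     anchor_duration)


@dataclass(frozen=True)
class EncodingScheme:
    """Timing and sign matrix of a Hadamard time-encoded labeling train.

    Parameters
    ----------
    base_pld : float
        Delay between end of the labeling train and readout (s).
    block_durations : tuple of float
        Sub-bolus durations in play order, first-played first (s).
    label_efficiency_alpha : float
        Labeling efficiency of the pCASL train (dimensionless).
    t1_blood : float
        Arterial blood T1 used for compensation arithmetic (s).
    """

    base_pld: float
    block_durations: tuple
    label_efficiency_alpha: float = 0.85
    t1_blood: float = DEFAULT_T1_BLOOD_S
    encoding_matrix: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        tau = tuple(float(t) for t in self.block_durations)
        object.__setattr__(self, "block_durations", tau)
        if any(t <= 0 for t in tau):
            raise ValueError("all block durations must be positive")
        if not 0 < self.label_efficiency_alpha <= 1:
            raise ValueError("label_efficiency_alpha must be in (0, 1]")
        if self.base_pld < 0:
            raise ValueError("base_pld must be non-negative")
        if self.encoding_matrix is None:
            object.__setattr__(
                self, "encoding_matrix", build_hadamard_matrix(len(tau))
            )
        m = np.asarray(self.encoding_matrix)
        if m.shape != (len(tau) + 1, len(tau)):
            raise ValueError(
                f"encoding_matrix shape {m.shape} does not match "
                f"{len(tau)} blocks (expected {(len(tau) + 1, len(tau))})"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.block_durations)

    @property
    def n_encodings(self) -> int:
        return self.n_blocks + 1

    @property
    def effective_plds(self) -> np.ndarray:
        return effective_plds(self.base_pld, self.block_durations)

    @property
    def label_duration(self) -> float:
        """Total labeling-train duration (s)."""
        return float(np.sum(self.block_durations))

    @property
    def prep_duration(self) -> float:
        """Label train plus base PLD: the window available for BS pulses (s)."""
        return self.label_duration + self.base_pld

    def delivered_signal_weights(self) -> np.ndarray:
        return delivered_signal_weights(
            self.base_pld, self.block_durations, self.t1_blood
        )

    @classmethod
    def design(
        cls,
        base_pld: float,
        n_blocks: int,
        t1_blood: float = DEFAULT_T1_BLOOD_S,
        anchor_duration: float | None = 0.224,
        total_duration: float | None = None,
        alpha: float = 0.85,
    ) -> "EncodingScheme":
        """Build a T1-compensated scheme from the equal-signal recurrence."""
        tau = design_t1_compensated_durations(
            base_pld, n_blocks, t1_blood, anchor_duration, total_duration
        )
        return cls(base_pld, tuple(tau), alpha, t1_blood)

    @classmethod
    def reference_seven_block(cls, alpha: float = 0.85) -> "EncodingScheme":
        """The seven-block scheme with 500 ms base PLD and block durations
        1175/683/482/374/305/257/224 ms (play order), giving effective PLDs
        2825/2142/1660/1286/981/724/500 ms."""
        return cls(REFERENCE_BASE_PLD_S, REFERENCE_BLOCK_DURATIONS_S, alpha)

    # -- serialization --------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = {
            "base_pld_s": float(self.base_pld),
            "block_durations_s": [float(t) for t in self.block_durations],
            "t1_blood_s": float(self.t1_blood),
            "alpha": float(self.label_efficiency_alpha),
            "matrix_order": self.n_encodings,
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "EncodingScheme":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    doc = yaml.safe_load(fh)
            except (OSError, ValueError):
                doc = yaml.safe_load(source)
        return cls(
            base_pld=float(doc["base_pld_s"]),
            block_durations=tuple(doc["block_durations_s"]),
            label_efficiency_alpha=float(doc.get("alpha", 0.85)),
            t1_blood=float(doc.get("t1_blood_s", DEFAULT_T1_BLOOD_S)),
        )


# ---------------------------------------------------------------------------
# Background suppression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackgroundSuppressionPlan:
    """Inversion-pulse timing that nulls static tissue at readout.

    ``pulse_times`` are seconds after the start of the preparation window
    (label-train onset, where static tissue is modeled as saturated).
    ``achieved_residuals`` is end-of-window Mz per compartment, as a signed
    fraction of equilibrium.
    """

    prep_duration: float
    pulse_times: tuple
    target_residual: float
    compartment_t1s: tuple
    achieved_residuals: tuple
    objective: float
    objective_kind: str = "minimax"

    def __post_init__(self):
        t = tuple(float(x) for x in self.pulse_times)
        object.__setattr__(self, "pulse_times", t)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("pulse_times must be strictly ascending")
        if t and (t[0] < 0 or t[-1] > self.prep_duration):
            raise ValueError("pulse_times must lie inside [0, prep_duration]")
        if any(abs(r) > 1 + 1e-12 for r in self.achieved_residuals):
            raise ValueError("achieved residuals must lie in [-1, 1]")


def simulate_mz(pulse_times, window: float, t1, initial_mz: float = 0.0):
    """Longitudinal magnetization at the end of the preparation window.

    Static tissue starts at ``initial_mz`` (default 0: saturated by the
    labeling train onset), relaxes toward equilibrium (+1) with time constant
    ``t1``, and is ideally inverted (Mz -> -Mz) at each pulse time.

    ``pulse_times`` may be an array of shape ``(..., n_pulses)`` (each row
    ascending); ``t1`` may be a scalar or 1-D array of compartments.  Returns
    Mz with shape ``broadcast(..., t1)``.
    """
    raw = np.asarray(pulse_times, dtype=float)
    times = np.atleast_2d(raw)
    t1 = np.asarray(t1, dtype=float)
    scalar_t1 = t1.ndim == 0
    t1 = np.atleast_1d(t1)[..., None, None]  # (n_t1, 1, 1) vs times (..., k)
    mz = np.full(np.broadcast_shapes(t1.shape[:-1], times.shape[:-1]),
                 float(initial_mz))
    prev = np.zeros(times.shape[:-1])
    for k in range(times.shape[-1]):
        dt = times[..., k] - prev
        mz = 1.0 - (1.0 - mz) * np.exp(-dt / t1[..., 0])
        mz = -mz
        prev = times[..., k]
    mz = 1.0 - (1.0 - mz) * np.exp(-(window - prev) / t1[..., 0])
    if raw.ndim == 1:
        mz = mz[..., 0]  # single pulse-time vector: drop the candidate axis
    if scalar_t1:
        mz = mz[0] if mz.ndim else mz
    return mz


def _bs_objective(times, window, t1s, target, kind="minimax"):
    """Deviation of end-of-window Mz from the target residual.

    ``kind="minimax"``: worst compartment's |Mz - target| (equalizes the
    residual across compartments); ``kind="ssq"``: sum of squared deviations.
    ``times`` of shape (n_candidates, n_pulses) -> vector of objectives;
    a single 1-D pulse-time vector -> scalar.
    """
    x = np.asarray(times, dtype=float)
    mz = np.atleast_2d(simulate_mz(np.atleast_2d(x), window, t1s))
    dev = np.abs(mz - target)  # (n_t1, n_cand)
    obj = dev.max(axis=0) if kind == "minimax" else np.sum(dev**2, axis=0)
    return float(obj[0]) if x.ndim == 1 else obj


def optimize_background_suppression(
    prep_duration: float,
    compartment_t1s,
    target_residual: float = 0.10,
    n_pulses: int = 2,
    coarse_step: float = 0.02,
    objective: str = "minimax",
) -> BackgroundSuppressionPlan:
    """Place BS inversion pulses to hit a residual Mz target at readout.

    Minimizes the deviation of end-of-window Mz from ``+target_residual``
    across the tissue compartments, assuming ideal instantaneous inversions
    and saturation at window start.  The default ``minimax`` objective
    (worst compartment's absolute deviation) equalizes the residual across
    compartments, matching the design intent of an equal residual for every
    tissue; ``objective="ssq"`` minimizes the sum of squares instead.
    Deterministic: an exhaustive coarse grid over ordered pulse-time tuples
    followed by a Nelder-Mead polish (final resolution well below 0.1 ms).
    """
    if objective not in ("minimax", "ssq"):
        raise ValueError("objective must be 'minimax' or 'ssq'")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if not 0 < target_residual <= 1:
        raise ValueError("target_residual must be in (0, 1]")
    if prep_duration <= 0:
        raise ValueError("prep_duration must be positive")
    resolution = 1e-4
    if n_pulses * resolution >= prep_duration:
        raise ValueError(
            f"{n_pulses} pulses cannot be strictly ordered within a "
            f"{prep_duration} s window at {resolution * 1e3:.1f} ms resolution"
        )
    t1s = np.asarray(compartment_t1s, dtype=float)
    if t1s.ndim != 1 or t1s.size == 0 or np.any(t1s <= 0):
        raise ValueError("compartment_t1s must be a non-empty list of positive T1s")

    # coarse exhaustive search over ascending pulse-time tuples
    grid = np.arange(coarse_step, prep_duration, coarse_step)
    idx = np.array(list(itertools.combinations(range(grid.size), n_pulses)))
    cand = grid[idx]  # (n_comb, n_pulses)
    objs = _bs_objective(cand, prep_duration, t1s, target_residual, objective)
    k = int(np.argmin(objs))
    best_t, best_obj = cand[k], float(objs[k])

    # local polish; keep ordering via penalty
    def penalized(x):
        if np.any(np.diff(x) <= 0) or x[0] <= 0 or x[-1] >= prep_duration:
            return 1e6
        return _bs_objective(x, prep_duration, t1s, target_residual, objective)

    res = minimize(
        penalized, best_t, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-15, "maxiter": 8000},
    )
    if res.fun <= best_obj:
        times, obj = np.sort(res.x), float(res.fun)
    else:
        times, obj = best_t, best_obj
    achieved = simulate_mz(times, prep_duration, t1s)
    return BackgroundSuppressionPlan(
        prep_duration=float(prep_duration),
        pulse_times=tuple(times),
        target_residual=float(target_residual),
        compartment_t1s=tuple(t1s),
        achieved_residuals=tuple(np.atleast_1d(achieved)),
        objective=obj,
        objective_kind=objective,
    )
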