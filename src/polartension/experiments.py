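"""In-silico experiments and polarity analytics.

Drivers for the simulated assays: polarization detection and timing,
stimulus-threshold searches, the random-switching stability assay
(n_p/n_s), micropipette aspiration–release, pseudopod severing,
parameter-sensitivity analysis, the initial-condition ensemble, and
dual-stimulus front competition.

Operating conventions (see docs/methods.md for rationale):

* A cell counts as *polarized* when the membrane maximum of Rac-GTP exceeds
  the separatrix midpoint (u_L+u_H)/2 of the bistable kinetics and stays
  above it to the end of the trace; the polarization time is the first
  upward crossing after stimulus onset.
* The polarity angle is the direction of the B(φ)-weighted first circular
  moment of u about the cell center.
* A stimulus event redirects the cell when the post-event polarity angle
  lies within 45° of the event's direction and the pre-event angle did not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .params import ModelParams
from .geometry import PhaseFieldGeometry, make_disk, make_tethered, sever
from .kinetics import membrane_tension, well_mixed_fixed_points
from .solver import (CellState, SolverConfig, SimulationTrace, Stepper,
                     homogeneous_state, simulate, weighted_polarity_angle)
from .stimuli import (StimulusProtocol, StimulusEvent, make_ks_function,
                      switching_schedule, graded_pattern)

polarity_angle = weighted_polarity_angle


# ---------------------------------------------------------------------------
# reference kinetic levels

def reference_levels(params: ModelParams) -> tuple[float, float]:
    """(u_L, u_H) anchoring the polarization criterion.

    u_L is the resting Rac-GTP level, found self-consistently with the
    resting Rac-GDP pool (total Rac mass u0+v0 is conserved and almost all
    of it sits in the cytosolic pool at rest).  u_H is the high stable level
    at the polarized operating point, evaluated at the background pool v*
    implied by the printed steady-state Rac-GTP total and the tension of the
    pinned front.  Both are well-mixed quantities; the separatrix midpoint
    (u_L+u_H)/2 is the polarization criterion used by the experiments.
    """
    # resting state: v_rest = u0 + v0 - u_L, iterate twice (converges fast)
    uL = 0.07 * params.u0 / 2.0
    for _ in range(3):
        v_rest = params.u0 + params.v0 - uL
        fp = well_mixed_fixed_points(v_rest, params, mt=params.mt0)
        stable = [r for r, s in zip(fp.roots, fp.stable) if s]
        uL = stable[0]
    # polarized operating point: front pinned at elevated tension; the
    # pinned state carries ~3.7% of the Rac pool as Rac-GTP, and the
    # closure's effective operating tension sits ~1.05 pN/μm above basal
    # (the Maxwell-balance point of the front-level kinetics)
    v_op = (params.u0 + params.v0) * (1.0 - 0.037)
    mt_op = params.mt0 + 1.05
    try:
        fp = well_mixed_fixed_points(v_op, params, mt=mt_op)
        stable = [r for r, s in zip(fp.roots, fp.stable) if s]
        uH = stable[-1]
    except RuntimeError:
        uH = 0.52
    if uH < 2.5 * uL:   # operating point not bistable; fall back to basal mt
        fp = well_mixed_fixed_points(v_op, params, mt=params.mt0)
        stable = [r for r, s in zip(fp.roots, fp.stable) if s]
        uH = stable[-1]
    return uL, uH


def polarization_threshold_value(params: ModelParams,
                                 u_H: float | None = None,
                                 u_L: float | None = None) -> float:
    """Separatrix midpoint (u_L+u_H)/2 used as the polarized criterion."""
    if u_H is None or u_L is None:
        u_L, u_H = reference_levels(params)
    return 0.5 * (u_L + u_H)


# ---------------------------------------------------------------------------
# detection

@dataclass
class PolarizationCall:
    polarized: bool
    polarization_time: Optional[float]   # s from stimulus onset, or None


def detect_polarization(trace: SimulationTrace, u_H: float,
                        tol_frac: float = 0.05, *,
                        u_L: float | None = None,
                        stimulus_onset: float = 0.0) -> PolarizationCall:
    """Decide whether a trace reaches and holds the polarized branch.

    The cell is polarized when max_u exceeds the threshold — the separatrix
    midpoint (u_L+u_H)/2 when ``u_L`` is given, else (1−tol_frac)·u_H — and
    remains above it to the end of the trace.  The polarization time is the
    first crossing after ``stimulus_onset``.
    """
    if not (0.0 < tol_frac <= 0.2):
        raise ValueError("tol_frac must lie in (0, 0.2]")
    t = np.asarray(trace.times, dtype=float)
    m = np.asarray(trace.max_u, dtype=float)
    if t.size < 2:
        raise ValueError("trace too short to classify")
    thr = 0.5 * (u_L + u_H) if u_L is not None else (1.0 - tol_frac) * u_H
    after = t >= stimulus_onset
    above = m >= thr
    idx = np.nonzero(above & after)[0]
    if idx.size == 0 or not above[-1]:
        return PolarizationCall(False, None)
    # require the final crossing to hold to the end
    first_hold = idx[0]
    for i in idx:
        if above[i:].all():
            first_hold = i
            break
    else:
        return PolarizationCall(False, None)
    return PolarizationCall(True, float(t[first_hold] - stimulus_onset))


# ---------------------------------------------------------------------------
# polarization runs and thresholds

def polarization_run(params: ModelParams, ks_amp: float, ks_dur: float,
                     *, direction: int = 0, t_end: float = 400.0,
                     geometry: PhaseFieldGeometry | None = None,
                     initial: CellState | None = None,
                     config: SolverConfig | None = None,
                     stimulus_onset: float = 0.0,
                     from_rest: bool = False,
                     rest_t: float = 250.0) -> SimulationTrace:
    """Graded-stimulus polarization assay.

    Starts from the homogeneous initial state (u0, v0, f0); with
    ``from_rest`` the cell is first relaxed for ``rest_t`` seconds so the
    stimulus acts on the resting state u_L rather than on the critically
    poised initial transient (stimulus thresholds are only well defined
    from rest).
    """
    g = geometry if geometry is not None else make_disk(params)
    st = initial.copy() if initial is not None else homogeneous_state(g, params)
    if from_rest and initial is None:
        pre_cfg = (_with_tend(config, rest_t) if config is not None
                   else SolverConfig(dt=params.dt, t_end=rest_t,
                                     snapshot_every=max(1, int(2.0 / params.dt))))
        st = simulate(st, g, params, None, pre_cfg).final_state
    proto = StimulusProtocol(kind="graded", ks_amp=ks_amp, ks_dur=ks_dur,
                             direction=direction, R=params.R,
                             t_on=stimulus_onset + st.t)
    if config is not None:
        cfg = _with_tend(config, st.t + t_end)
    else:
        cfg = SolverConfig(dt=params.dt, t_end=st.t + t_end,
                           snapshot_every=max(1, int(2.0 / params.dt)))
    return simulate(st, g, params, make_ks_function(proto, g), cfg)


def threshold_search(params: ModelParams, ks_dur: float,
                     bracket: tuple[float, float] = (1e-4, 0.05), *,
                     rel_tol: float = 0.02, t_end: float = 400.0,
                     geometry: PhaseFieldGeometry | None = None,
                     vary: str = "amp", ks_amp: float | None = None,
                     config: SolverConfig | None = None) -> float:
    """Bisect the stimulus amplitude (or duration) needed for polarization.

    The assay starts from the rested state (see ``polarization_run``),
    where the threshold is well defined.  ``vary='amp'`` fixes the duration
    and searches the amplitude; ``vary='dur'`` fixes ``ks_amp`` and
    searches the duration.  Raises ``RuntimeError`` with both endpoint
    outcomes when the bracket does not straddle the threshold.
    """
    g = geometry if geometry is not None else make_disk(params)
    u_L, u_H = reference_levels(params)

    def polarized(x: float) -> bool:
        amp, dur = (x, ks_dur) if vary == "amp" else (ks_amp, x)
        tr = polarization_run(params, amp, dur, t_end=t_end, geometry=g,
                              config=config, from_rest=True)
        return detect_polarization(tr, u_H, u_L=u_L).polarized

    lo, hi = bracket
    lo_pol, hi_pol = polarized(lo), polarized(hi)
    if lo_pol or not hi_pol:
        raise RuntimeError(
            f"bracket does not straddle the threshold: outcome({lo})="
            f"{lo_pol}, outcome({hi})={hi_pol}")
    while (hi - lo) / hi > rel_tol:
        mid = math.sqrt(lo * hi)   # geometric bisection: thresholds span decades
        if polarized(mid):
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


def threshold_search_dur(params: ModelParams, ks_amp: float,
                         bracket: tuple[float, float] = (1.0, 200.0),
                         **kw) -> float:
    return threshold_search(params, ks_dur=0.0, bracket=bracket,
                            vary="dur", ks_amp=ks_amp, **kw)


def threshold_product_ratio(params: ModelParams, mt0_low: float,
                            mt0_high: float, ks_dur: float, **kw) -> float:
    """Fold change of the stimulus-strength product ks_amp*·ks_dur between
    two basal tensions at equal duration (reduces to the amplitude ratio)."""
    thr_low = threshold_search(params.with_updates(mt0=mt0_low), ks_dur, **kw)
    thr_high = threshold_search(params.with_updates(mt0=mt0_high), ks_dur, **kw)
    return (thr_high * ks_dur) / (thr_low * ks_dur)


@dataclass
class ThresholdCurve:
    mt0: float
    points: list = field(default_factory=list)   # (ks_amp, ks_dur) pairs
    search_tolerance: float = 0.02

    def validate_hyperbola_like(self) -> bool:
        """Larger amplitudes pair with shorter-or-equal threshold durations."""
        pts = sorted(self.points)
        return all(d2 <= d1 + 1e-9 for (_, d1), (_, d2) in zip(pts, pts[1:]))


def threshold_curve(params: ModelParams, durations: Sequence[float],
                    **kw) -> ThresholdCurve:
    curve = ThresholdCurve(mt0=params.mt0,
                           search_tolerance=kw.get("rel_tol", 0.02))
    for dur in durations:
        amp = threshold_search(params, dur, **kw)
        curve.points.append((amp, dur))
    return curve


# ---------------------------------------------------------------------------
# stability under random switching stimuli

@dataclass
class StabilityResult:
    n_s: int
    n_p: int
    seed: int
    mt0: float

    @property
    def ratio(self) -> float:
        return self.n_p / self.n_s if self.n_s else float("nan")


def _angular_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def stability_experiment(params: ModelParams, *, seed: int,
                         n_events: int = 10,
                         amp_range: tuple[float, float] = (0.004, 0.02),
                         dur_range: tuple[float, float] = (15.0, 50.0),
                         gap: float = 60.0,
                         redirect_tol: float = 45.0,
                         warm_state: CellState | None = None,
                         warm_amp: float = 0.01, warm_dur: float = 25.0,
                         warm_t: float = 300.0,
                         geometry: PhaseFieldGeometry | None = None,
                         config: SolverConfig | None = None
                         ) -> StabilityResult:
    """Random four-direction switching assay: count stimulus redirections
    n_s and polarity redirections n_p for one seed.

    The cell is first polarized toward 0° (or a pre-polarized ``warm_state``
    is supplied and reused across seeds); the schedule then applies
    ``n_events`` graded stimuli with random amplitude, duration and
    direction.  n_s counts events whose direction differs from the previous
    event's (the first event is compared with the initial polarity); n_p
    counts those events after which the polarity angle lies within
    ``redirect_tol`` of the event direction while the pre-event angle did not.
    """
    g = geometry if geometry is not None else make_disk(params)
    cfg = config or SolverConfig(dt=params.dt, t_end=0.0,
                                 snapshot_every=max(1, int(2.0 / params.dt)))
    stepper = Stepper(g, params, cfg)
    if warm_state is None:
        tr = polarization_run(params, warm_amp, warm_dur, t_end=warm_t,
                              geometry=g, config=_with_tend(cfg, warm_t))
        state = tr.final_state
        u_L, u_H = reference_levels(params)
        if tr.max_u[-1] < 0.5 * (u_L + u_H):
            raise RuntimeError("cell failed to polarize during warm-up")
    else:
        state = warm_state.copy()

    sched = switching_schedule(seed, n_events, amp_range, dur_range,
                               t_start=state.t, gap=gap)
    ang0 = weighted_polarity_angle(state.u, g)
    prev_dir: float = ang0 if not math.isnan(ang0) else 0.0
    n_s = n_p = 0
    for ev in sched:
        proto = StimulusProtocol(kind="switching_sequence", R=params.R,
                                 schedule=[ev])
        ks = make_ks_function(proto, g)
        pre_angle = weighted_polarity_angle(state.u, g)
        tr = simulate(state, g, params, ks,
                      _with_tend(cfg, ev.offset + _gap_after(ev, sched, gap)),
                      stepper=stepper)
        state = tr.final_state
        post_angle = weighted_polarity_angle(state.u, g)
        counts_s = _angular_dist(ev.direction, prev_dir) > 1.0
        if counts_s:
            n_s += 1
            pre_ok = (not math.isnan(pre_angle)) and \
                _angular_dist(pre_angle, ev.direction) <= redirect_tol
            post_ok = (not math.isnan(post_angle)) and \
                _angular_dist(post_angle, ev.direction) <= redirect_tol
            if post_ok and not pre_ok:
                n_p += 1
            prev_dir = ev.direction
        else:
            prev_dir = ev.direction
    return StabilityResult(n_s=n_s, n_p=n_p, seed=seed, mt0=params.mt0)


def _with_tend(cfg: SolverConfig, t_end: float) -> SolverConfig:
    from dataclasses import replace
    return replace(cfg, t_end=t_end)


def _gap_after(ev: StimulusEvent, sched: list, gap: float) -> float:
    i = sched.index(ev)
    if i + 1 < len(sched):
        return sched[i + 1].onset - ev.offset
    return gap


@dataclass
class StabilityEnsemble:
    results: list
    mean_ratio: float
    sd_ratio: float
    mt0: float


def stability_ensemble(params: ModelParams, seeds: Sequence[int],
                       **kw) -> StabilityEnsemble:
    """Run the switching assay over seeds, sharing one warm-up state.

    When ``warm_mt0`` is given, the cell is polarized at that (lower) basal
    tension and the tension is then raised to ``params.mt0`` with a
    relaxation period — high-tension cells hold an established front even
    when de-novo polarization at that tension is suppressed.
    """
    g = kw.pop("geometry", None) or make_disk(params)
    cfg = kw.pop("config", None) or SolverConfig(
        dt=params.dt, t_end=0.0, snapshot_every=max(1, int(2.0 / params.dt)))
    warm_amp = kw.pop("warm_amp", 0.01)
    warm_dur = kw.pop("warm_dur", 25.0)
    warm_t = kw.pop("warm_t", 300.0)
    warm_mt0 = kw.pop("warm_mt0", None)
    warm_params = params if warm_mt0 is None else params.with_updates(mt0=warm_mt0)
    tr = polarization_run(warm_params, warm_amp, warm_dur, t_end=warm_t,
                          geometry=g, config=_with_tend(cfg, warm_t))
    if warm_mt0 is not None:
        tr = simulate(tr.final_state, g, params, None,
                      _with_tend(cfg, warm_t + 300.0))
    u_L, u_H = reference_levels(params)
    if tr.max_u[-1] < 0.5 * (u_L + u_H):
        raise RuntimeError("ensemble warm-up failed to polarize")
    warm = tr.final_state
    results = [stability_experiment(params, seed=s, warm_state=warm,
                                    geometry=g, config=cfg, **kw)
               for s in seeds]
    ratios = [r.ratio for r in results if r.n_s > 0]
    return StabilityEnsemble(results=results,
                             mean_ratio=float(np.mean(ratios)),
                             sd_ratio=float(np.std(ratios, ddof=1))
                             if len(ratios) > 1 else 0.0,
                             mt0=params.mt0)


# ---------------------------------------------------------------------------
# aspiration–release

def aspiration_release(params: ModelParams, *, tension_multiplier: float = 10.0,
                       t_aspirate: float = 400.0, t_release: float = 460.0,
                       t_end: float = 800.0,
                       warm_amp: float = 0.01, warm_dur: float = 25.0,
                       noise_amp: float = 0.002, noise_seed: int = 0,
                       geometry: PhaseFieldGeometry | None = None,
                       config: SolverConfig | None = None) -> SimulationTrace:
    """Micropipette assay: polarize, instantly raise tension at
    ``t_aspirate`` (mt ← multiplier·mt(f)), restore the tension–F-actin
    relationship at ``t_release``; the trace shows collapse and recovery.

    A sustained sub-threshold local-random stimulus (``noise_amp``) runs
    throughout, mirroring the background perturbations of the severing
    protocol; it cannot redirect or depolarize the cell on its own but
    reseeds the front after release while a remnant of the F-actin
    asymmetry survives.
    """
    if t_release <= t_aspirate:
        raise ValueError("t_release must exceed t_aspirate")
    g = geometry if geometry is not None else make_disk(params)
    cfg = config or SolverConfig(dt=params.dt, t_end=t_end,
                                 snapshot_every=max(1, int(2.0 / params.dt)))

    def mt_policy(t: float, mt_from_f: float) -> float:
        if t_aspirate < t <= t_release:
            return mt_from_f * tension_multiplier
        return mt_from_f

    proto = StimulusProtocol(kind="graded", ks_amp=warm_amp, ks_dur=warm_dur,
                             direction=0, R=params.R)
    noise = StimulusProtocol(kind="local_random", ks_amp=noise_amp,
                             ks_dur=20.0, direction=0, seed=noise_seed,
                             R=params.R, repeat_until=t_end)
    ks_w = make_ks_function(proto, g)
    ks_n = make_ks_function(noise, g) if noise_amp > 0 else (lambda t: 0.0)

    def ks(t):
        a, b_ = ks_w(t), ks_n(t)
        if isinstance(a, float) and isinstance(b_, float):
            return 0.0
        return a + b_

    st = homogeneous_state(g, params)
    tr = simulate(st, g, params, ks, _with_tend(cfg, t_end),
                  mt_policy=mt_policy)
    tr.events.append((t_aspirate, "aspirate"))
    tr.events.append((t_release, "release"))
    return tr


def collapse_recovery_times(trace: SimulationTrace, t_aspirate: float,
                            t_release: float, u_L: float, u_H: float,
                            recovery_frac: float = 0.95
                            ) -> tuple[Optional[float], Optional[float]]:
    """Operational collapse/recovery timings for the aspiration assay.

    Decay time: from aspiration onset until max_u first falls below the
    bistable separatrix midpoint (u_L+u_H)/2 — the loss of the polarized
    state.  Recovery time: from release until max_u first returns to
    ``recovery_frac`` of its pre-aspiration level.  None when the trace
    never crosses the respective level.
    """
    t = np.asarray(trace.times)
    m = np.asarray(trace.max_u)
    mid = 0.5 * (u_L + u_H)
    pre = m[t <= t_aspirate]
    pre_level = pre[-1] if pre.size else u_H
    decay = recovery = None
    idx = np.nonzero((t > t_aspirate) & (m <= mid))[0]
    if idx.size:
        decay = float(t[idx[0]] - t_aspirate)
    idx2 = np.nonzero((t > t_release) & (m >= recovery_frac * pre_level))[0]
    if idx2.size:
        recovery = float(t[idx2[0]] - t_release)
    return decay, recovery


# ---------------------------------------------------------------------------
# severing

@dataclass
class SeveringOutcome:
    front_trace: SimulationTrace
    body_trace: SimulationTrace
    body_polarized: bool
    body_cv_before: float       # coefficient of variation of body F-actin


def severing_experiment(params: ModelParams, *, release_tension: bool,
                        noise_amp: float = 0.012, seed: int = 0,
                        t_sever: float = 60.0, t_end: float = 700.0,
                        body_radius: float = 6.0, neck_length: float = 10.0,
                        neck_halfwidth: float = 1.0, pseudopod_radius: float = 3.5,
                        warm_amp: float = 0.01, warm_dur: float = 40.0,
                        config: SolverConfig | None = None) -> SeveringOutcome:
    """Sever a polarized pseudopod–neck–body cell at the neck.

    The assay starts from the steady tethered morphology — Rac-GTP and
    F-actin concentrated at the pseudopod, the body at the resting level —
    constructed directly and relaxed under a pseudopod-restricted graded
    stimulus; sustained sub-threshold local-random stimuli act on the body
    throughout.  At ``t_sever`` the shape is cut mid-neck; with
    ``release_tension`` the body recomputes its tension from its own
    F-actin, otherwise the body keeps the pre-cut tension.  The body trace
    shows whether new polarity forms.
    """
    g = make_tethered(params, body_radius=body_radius, neck_length=neck_length,
                      neck_halfwidth=neck_halfwidth,
                      pseudopod_radius=pseudopod_radius)
    cfg = config or SolverConfig(dt=params.dt, t_end=t_sever,
                                 snapshot_every=max(1, int(2.0 / params.dt)))
    extent = 2 * body_radius + neck_length + 2 * pseudopod_radius
    x_body = -(extent / 2.0 - body_radius)
    x_pod = extent / 2.0 - pseudopod_radius
    cut_x = 0.5 * ((x_body + body_radius) + (x_pod - pseudopod_radius))
    X, _ = g.meshgrid()

    # constructed pod-polarized initial state at full concentration values;
    # the pod's F-actin load is scaled so the initial membrane tension sits
    # at the stall value of the wall kinetics (~mt0 + 1.7), which keeps the
    # front pinned at the pseudopod instead of creeping through the neck
    u_L, u_H = reference_levels(params)
    pod = X > x_pod - pseudopod_radius
    support = g.phi > 1e-3
    u = np.where(pod, u_H, u_L) * support
    f_raw = np.where(pod, 1.0, 0.0) * support
    F_raw = float(np.sum(g.phi * f_raw)) * g.dA
    mt_target = params.mt0 + 1.7
    F_needed = (mt_target / params.mt0 - 1.0) / max(params.lam, 1e-12)
    f = f_raw * (F_needed / F_raw)
    v = (params.u0 + params.v0 - u_L) * np.ones_like(u)
    st = CellState(u=u, v=v, f=f)
    st.mt = membrane_tension(f, g, params)

    # pseudopod-restricted graded stimulus maintains the front during the
    # relaxation; sub-threshold random noise acts on the body side
    warm_pattern = warm_amp * np.clip(params.R + X, 0.0, None)
    warm_pattern *= (X > cut_x) & g.interior_mask()
    # noise starts once the pseudopod front's tension has built up enough
    # to keep the body sub-threshold (half-way to the cut)
    noise = StimulusProtocol(kind="local_random", ks_amp=noise_amp,
                             ks_dur=20.0, direction=180, region_fraction=0.25,
                             seed=seed, R=params.R, t_on=0.5 * t_sever,
                             repeat_until=t_end)
    ks_n = make_ks_function(noise, g)

    def ks_both(t):
        a = warm_pattern if 0 < t <= warm_dur else 0.0
        b = ks_n(t)
        if isinstance(a, float) and isinstance(b, float):
            return 0.0
        return a + b

    tr = simulate(st, g, params, ks_both, _with_tend(cfg, t_sever))
    pre = tr.final_state

    # body uniformity before the cut (left of the neck)
    body_mask = (g.phi > 0.5) & (X < x_body + body_radius)
    f_body = pre.f[body_mask]
    cv = float(np.std(f_body) / np.mean(f_body)) if np.mean(f_body) > 0 else 0.0
    if float(pre.u[body_mask].max()) > 0.5 * (u_L + u_H):
        raise RuntimeError("fixture invalid: body polarized before the cut")

    front_g, body_g = sever(g, cut_x)
    mt_pre = pre.mt

    def restrict(geom):
        s = pre.copy()
        mask = geom.phi > 1e-3
        s.u = np.where(mask, s.u, 0.0)
        s.v = np.where(mask, s.v, 0.0)
        s.f = np.where(mask, s.f, 0.0)
        s.mt = membrane_tension(s.f, geom, params)
        return s

    front_state = restrict(front_g)
    body_state = restrict(body_g)
    noise_body = StimulusProtocol(kind="local_random", ks_amp=noise_amp,
                                  ks_dur=20.0, direction=180,
                                  region_fraction=0.25, seed=seed + 1,
                                  R=params.R, t_on=t_sever,
                                  repeat_until=t_end)
    ks_nb = make_ks_function(noise_body, body_g)
    mt_policy = None if release_tension else (lambda t, mtf: mt_pre)
    from dataclasses import replace as _dc_replace
    cfg_fields = _dc_replace(cfg, store_fields=True,
                             snapshot_every=max(cfg.snapshot_every, 200))
    body_tr = simulate(body_state, body_g, params, ks_nb,
                       _with_tend(cfg_fields, t_end), mt_policy=mt_policy)
    front_tr = simulate(front_state, front_g, params, None,
                        _with_tend(cfg, t_end))

    # polarity of the body DISK proper: the severed body piece includes a
    # stub of the neck that may carry residual activity, so the detection
    # trace is the Rac-GTP maximum restricted to the body disk
    disk_mask = (body_g.phi > 0.5) & (X < x_body + body_radius)
    disk_tr = SimulationTrace()
    disk_tr.times = [t for t, _ in body_tr.snapshots]
    disk_tr.max_u = [float(s_.u[disk_mask].max()) for _, s_ in body_tr.snapshots]

    u_L, u_H = reference_levels(params)
    # the new-polarity call requires the body disk to reach the polarized
    # branch proper ((1−tol)·u_H), not merely the separatrix: slow leakage
    # from the residual neck stub must not count as polarity
    call = detect_polarization(disk_tr, u_H, tol_frac=0.1,
                               stimulus_onset=t_sever)
    body_tr.snapshots = body_tr.snapshots[-1:]    # keep memory bounded
    return SeveringOutcome(front_trace=front_tr, body_trace=body_tr,
                           body_polarized=call.polarized, body_cv_before=cv)


# ---------------------------------------------------------------------------
# sensitivity analysis

def sensitivity_analysis(params: ModelParams, *,
                         perturbation_frac: float = 0.30,
                         parameters: Sequence[str] = (
                             "b", "r", "c1", "K1", "c2", "K2", "c3", "K3",
                             "d_f", "K_F", "lam", "D_u", "D_v", "D_f"),
                         warm_amp: float = 0.01, warm_dur: float = 25.0,
                         t_end: float = 400.0,
                         geometry: PhaseFieldGeometry | None = None,
                         config: SolverConfig | None = None) -> dict:
    """±perturbation_frac one-at-a-time sensitivity of the steady polarized
    max_u; returns {parameter: max |relative change|} with failed runs
    flagged as +inf."""
    g = geometry if geometry is not None else make_disk(params)

    def steady_max(p: ModelParams) -> float:
        tr = polarization_run(p, warm_amp, warm_dur, t_end=t_end,
                              geometry=g, config=config)
        return tr.max_u[-1]

    base = steady_max(params)
    out = {}
    for name in parameters:
        worst = 0.0
        for sign in (-1.0, 1.0):
            val = getattr(params, name) * (1.0 + sign * perturbation_frac)
            try:
                pert = params.with_updates(**{name: val})
                change = abs(steady_max(pert) - base) / base
            except (ValueError, RuntimeError, FloatingPointError):
                change = float("inf")
            worst = max(worst, change)
        out[name] = worst
    return out


# ---------------------------------------------------------------------------
# initial-condition ensemble

def noisy_initial_state(geometry: PhaseFieldGeometry, params: ModelParams,
                        seed: int, noise_sd: float = 0.1) -> CellState:
    """Homogeneous state with independent Gaussian noise (mean 0, sd
    ``noise_sd``) added to u and v; clipped at zero."""
    rng = np.random.default_rng(seed)
    st = homogeneous_state(geometry, params)
    st.u = np.clip(st.u + rng.normal(0.0, noise_sd, st.u.shape), 0.0, None)
    st.v = np.clip(st.v + rng.normal(0.0, noise_sd, st.v.shape), 0.0, None)
    return st


@dataclass
class EnsembleStats:
    max_u_mean: float
    max_u_sd: float
    total_u_mean: float
    total_u_sd: float
    n_polarized: int
    n_replicates: int


def initial_condition_study(params: ModelParams, *, n_replicates: int = 5,
                            seed: int = 0, noise_var: float = 0.01,
                            ks_amp: float = 0.01, ks_dur: float = 25.0,
                            t_end: float = 600.0,
                            geometry: PhaseFieldGeometry | None = None,
                            config: SolverConfig | None = None) -> EnsembleStats:
    """Ensemble of polarization runs from Gaussian-noise initial conditions
    (variance ``noise_var`` on u and v); reports the steady maximum and
    total Rac-GTP at the end of each run."""
    g = geometry if geometry is not None else make_disk(params)
    u_L, u_H = reference_levels(params)
    maxes, totals, n_pol = [], [], 0
    sd = math.sqrt(noise_var)
    for i in range(n_replicates):
        st = noisy_initial_state(g, params, seed=seed + 1000 * i, noise_sd=sd)
        tr = polarization_run(params, ks_amp, ks_dur, t_end=t_end, geometry=g,
                              initial=st, config=config)
        maxes.append(tr.max_u[-1])
        totals.append(tr.total_u[-1])
        if detect_polarization(tr, u_H, u_L=u_L).polarized:
            n_pol += 1
    return EnsembleStats(
        max_u_mean=float(np.mean(maxes)),
        max_u_sd=float(np.std(maxes, ddof=1)) if n_replicates > 1 else 0.0,
        total_u_mean=float(np.mean(totals)),
        total_u_sd=float(np.std(totals, ddof=1)) if n_replicates > 1 else 0.0,
        n_polarized=n_pol, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# dual-stimulus competition

def count_membrane_fronts(state: CellState, geometry: PhaseFieldGeometry,
                          threshold: float, n_sectors: int = 72) -> int:
    """Number of connected membrane arcs with u above ``threshold``.

    The membrane ring is binned into angular sectors (max of u per sector)
    before thresholding, so the count is insensitive to the pixel ordering
    across the ring's finite thickness.
    """
    ring = geometry.Bphi > 0.25 * geometry.Bphi.max()
    X, Y = geometry.meshgrid()
    theta = np.arctan2(Y[ring], X[ring]) % (2 * np.pi)
    sector = np.minimum((theta / (2 * np.pi) * n_sectors).astype(int),
                        n_sectors - 1)
    u_ring = state.u[ring]
    u_sector = np.full(n_sectors, -np.inf)
    np.maximum.at(u_sector, sector, u_ring)
    high = u_sector > threshold
    if not high.any():
        return 0
    if high.all():
        return 1
    changes = int(np.sum(high != np.roll(high, 1)))
    return changes // 2


def dual_stimulus_competition(params: ModelParams, *, amp1: float = 0.012,
                              amp2: float = 0.009, ks_dur: float = 25.0,
                              t_rest: float = 250.0, t_end: float = 550.0,
                              geometry: PhaseFieldGeometry | None = None,
                              config: SolverConfig | None = None):
    """Two simultaneous opposite stimuli with amp1 > amp2 applied to a
    resting cell: two fronts form and the stronger one should absorb the
    weaker.  Returns (trace, front_counts, final_angle); the front count is
    evaluated on each stored snapshot and the final angle at ``t_end``.

    The cell is first relaxed to its resting state for ``t_rest`` so the
    two fronts nucleate as distinct arcs.
    """
    if amp1 <= amp2:
        raise ValueError("amp1 must exceed amp2")
    g = geometry if geometry is not None else make_disk(params)
    cfg = config or SolverConfig(dt=params.dt, t_end=t_end,
                                 snapshot_every=max(1, int(2.0 / params.dt)),
                                 store_fields=True)
    st = homogeneous_state(g, params)
    rest_tr = simulate(st, g, params, None, _with_tend(cfg, t_rest))
    proto = StimulusProtocol(kind="dual_gradient", ks_amp=amp1, ks_amp2=amp2,
                             ks_dur=ks_dur, direction=0, R=params.R,
                             t_on=t_rest)
    tr = simulate(rest_tr.final_state, g, params, make_ks_function(proto, g),
                  _with_tend(cfg, t_end))
    u_L, u_H = reference_levels(params)
    thr = 0.5 * (u_L + u_H)
    counts = [(t, count_membrane_fronts(s, g, thr)) for t, s in tr.snapshots]
    final_angle = weighted_polarity_angle(tr.final_state.u, g)
    return tr, counts, final_angle
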