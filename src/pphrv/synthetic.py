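"""Simulated heartbeat series, chaotic surrogates and a full haptic protocol.

Every downstream stage of the package is testable without recorded data:

* :func:`simulate_ig_narl` runs the inverse-Gaussian NARL model forward with
  known parameters (sequential sampling of the next interval from the IG law
  whose mean comes from the NARL polynomial of the simulated history).
* Constant-parameter ("renewal") simulations draw i.i.d. IG intervals around
  a target mean -- the null of the model family.  The anchored NARL map is an
  integrated process by construction, so the renewal mode is what
  "constant-parameter simulation" means throughout the tests.
* :func:`simulate_protocol` emulates a stimulus protocol with two resting
  phases (2 min each), randomized stimuli of 2 force x 2 velocity levels with
  35 s pre/post windows and per-velocity durations of 25 s (slow) and 4.3 s
  (fast), injecting condition-dependent modulations of the mean interval,
  respiratory-band amplitude and IG shape during stimulus windows only.
* :func:`simulate_chaotic_rr` maps chaotic iterates (logistic, Henon) to
  positive pseudo-R-R intervals for Lyapunov validation, and
  :func:`synthesize_ecg` renders template-pulse ECG traces for the R-peak
  detector tests.

Condition effect sizes are fixture choices, not claims about physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .laguerre import LaguerreBasis, build_basis
from .pp_model import NARLParameters
from .rr_io import EventSeries, StimulusAnnotation

__all__ = [
    "GeneratorSpec",
    "ProtocolSpec",
    "ConditionEffect",
    "SubjectRecording",
    "simulate_ig_narl",
    "simulate_renewal",
    "simulate_protocol",
    "simulate_chaotic_rr",
    "synthesize_ecg",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a forward IG-NARL simulation.

    ``param_timeline`` is a piecewise-constant schedule: a list of
    ``(start_time, NARLParameters)`` pairs sorted by start time.  In
    ``mean_mode='anchored'`` the conditional mean is the model's own
    ``last_rr + NARL(l)``; in ``mean_mode='constant'`` the mean is ``g0`` of
    the active parameters directly (the renewal null).
    """

    param_timeline: tuple
    duration: float
    seed: int = 0
    initial_history: np.ndarray | None = None
    mean_mode: str = "anchored"
    alpha: float = 0.2
    num_functions: int = 3

    def params_at(self, t: float) -> NARLParameters:
        active = self.param_timeline[0][1]
        for start, p in self.param_timeline:
            if t >= start:
                active = p
            else:
                break
        return active


def simulate_ig_narl(spec: GeneratorSpec) -> EventSeries:
    """Sequentially sample an event series from the IG-NARL model.

    Deterministic given the seed.  Raises if the NARL mean ever becomes
    non-positive (the generator specification is then invalid).
    """
    if spec.duration <= 0:
        return EventSeries(event_times=np.array([]), t_end=0.0)
    rng = np.random.default_rng(spec.seed)
    basis = build_basis(spec.alpha, spec.num_functions)
    L = basis.truncation
    phi = basis.basis_matrix

    p0 = spec.param_timeline[0][1]
    mean0 = p0.g0 if spec.mean_mode == "constant" else 0.8
    if spec.initial_history is not None:
        hist = list(np.asarray(spec.initial_history, dtype=float))
    else:
        hist = [mean0] * (L + 2)
    times = [0.0]
    rr_hist = list(hist)
    while times[-1] < spec.duration:
        t = times[-1]
        params = spec.params_at(t)
        if spec.mean_mode == "constant":
            mu = params.g0
        else:
            drr = np.diff(rr_hist)
            window = drr[::-1][:L]
            l = phi[:, : window.size] @ window
            mu = rr_hist[-1] + params.g0
            p1 = params.g1.size
            if p1:
                mu += float(params.g1 @ l[:p1])
            p2 = params.g2.shape[0]
            if p2:
                l2 = l[:p2]
                mu += float(l2 @ params.g2 @ l2)
            if params.g3 is not None and params.g3.size:
                p3 = params.g3.shape[0]
                l3 = l[:p3]
                mu += float(np.einsum("ijk,i,j,k->", params.g3, l3, l3, l3))
        if mu <= 0:
            raise ValueError(
                f"NARL mean became non-positive at t={t:.3f}s; generator spec "
                "is invalid")
        w = float(rng.wald(mu, params.shape))
        times.append(t + w)
        rr_hist.append(w)
        if len(rr_hist) > L + 2:
            rr_hist.pop(0)
    return EventSeries(event_times=np.array(times[:-1]) if times[-1] > spec.duration
                       else np.array(times), t_end=spec.duration)


def simulate_renewal(mu, shape, duration: float, seed: int = 0) -> EventSeries:
    """Constant-(mu, xi0) renewal IG simulation (callables allowed).

    ``mu`` and ``shape`` may be scalars or callables of time, allowing
    deterministic modulation (respiratory-band oscillation, stimulus effects)
    with conditionally independent IG draws.
    """
    mu_fn = mu if callable(mu) else (lambda t: mu)
    sh_fn = shape if callable(shape) else (lambda t: shape)
    rng = np.random.default_rng(seed)
    times = [0.0]
    while times[-1] < duration:
        t = times[-1]
        m = float(mu_fn(t))
        s = float(sh_fn(t))
        if m <= 0 or s <= 0:
            raise ValueError(f"non-positive mu or shape at t={t:.3f}s")
        times.append(t + float(rng.wald(m, s)))
    u = np.array(times)
    if u[-1] > duration:
        u = u[:-1]
    return EventSeries(event_times=u, t_end=duration)


# ---------------------------------------------------------------------------
# stimulation protocol


@dataclass(frozen=True)
class ConditionEffect:
    """Modulation applied inside a stimulus window.

    ``dmu`` shifts the mean interval (s), ``hf_scale`` scales the
    respiratory-band amplitude, ``xi0_scale`` scales the IG shape.  Force and
    velocity effects combine (additive shifts, multiplicative scales).
    """

    dmu: float = 0.0
    hf_scale: float = 1.0
    xi0_scale: float = 1.0


_DEFAULT_EFFECTS = {
    "force_low": ConditionEffect(),
    "force_high": ConditionEffect(dmu=-0.030, hf_scale=0.80, xi0_scale=0.80),
    "velocity_slow": ConditionEffect(dmu=-0.020, hf_scale=0.75, xi0_scale=0.85),
    "velocity_fast": ConditionEffect(dmu=-0.120, hf_scale=0.20, xi0_scale=0.35),
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Simulated caress-stimulation protocol.

    Defaults mirror the study conditions: two 2-min rests, randomized stimuli
    of 2 force (2, 6 N) x 2 velocity (9.4, 65 mm/s) levels, 35 s pre/post
    windows, and per-velocity stimulus durations of 25 s (slow) and 4.3 s
    (fast), inside the 4.3-25 s range.
    """

    n_subjects: int = 32
    rest_duration: float = 120.0
    pre_post: float = 35.0
    force_levels: tuple = (2.0, 6.0)
    velocity_levels: tuple = (9.4, 65.0)
    slow_duration: float = 25.0
    fast_duration: float = 4.3
    repeats: int = 1
    mean_rr: float = 0.8
    xi0: float = 1500.0
    a_lf: float = 0.015
    a_hf: float = 0.025
    f_lf: float = 0.095
    f_hf: float = 0.25
    subject_mean_sd: float = 0.05
    subject_xi0_logsd: float = 0.2
    effects: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))


@dataclass(frozen=True)
class SubjectRecording:
    subject_id: str
    events: EventSeries
    annotations: tuple


def _protocol_timeline(spec: ProtocolSpec, rng: np.random.Generator,
                       subject_id: str) -> tuple[list[StimulusAnnotation], float]:
    kinds = [(f, v) for f in spec.force_levels for v in spec.velocity_levels]
    order = [kinds[i] for _ in range(spec.repeats)
             for i in rng.permutation(len(kinds))]
    t = spec.rest_duration
    anns = []
    for force, vel in order:
        dur = spec.fast_duration if vel == max(spec.velocity_levels) \
            else spec.slow_duration
        onset = t + spec.pre_post
        anns.append(StimulusAnnotation(onset=onset, offset=onset + dur,
                                       force_level=force, velocity_level=vel,
                                       subject_id=subject_id))
        t = onset + dur + spec.pre_post
    total = t + spec.rest_duration
    rest = ((0.0, spec.rest_duration), (total - spec.rest_duration, total))
    anns = [replace(a, rest_windows=rest) for a in anns]
    return anns, total


def simulate_protocol(spec: ProtocolSpec = ProtocolSpec(), seed: int = 0
                      ) -> list[SubjectRecording]:
    """Per-subject event series plus annotations for the default protocol.

    Subject heterogeneity: baseline mean interval ~ N(mean_rr, subject_mean_sd)
    and a log-normal shape multiplier.  Stimulus-window modulations come from
    ``spec.effects`` and vanish outside stimulus windows (rest baseline).
    """
    rng = np.random.default_rng(seed)
    recordings = []
    f_hi, v_hi = max(spec.force_levels), max(spec.velocity_levels)
    for s in range(spec.n_subjects):
        sid = f"s{s:02d}"
        anns, total = _protocol_timeline(spec, rng, sid)
        m0 = spec.mean_rr + spec.subject_mean_sd * rng.standard_normal()
        xi0_s = spec.xi0 * np.exp(spec.subject_xi0_logsd * rng.standard_normal())
        ph_lf, ph_hf = rng.uniform(0, 2 * np.pi, size=2)

        windows = [(a.onset, a.offset,
                    spec.effects["force_high" if a.force_level == f_hi
                                 else "force_low"],
                    spec.effects["velocity_fast" if a.velocity_level == v_hi
                                 else "velocity_slow"]) for a in anns]

        def active_effect(t):
            for onset, offset, ef, ev in windows:
                if onset <= t < offset:
                    return (ef.dmu + ev.dmu, ef.hf_scale * ev.hf_scale,
                            ef.xi0_scale * ev.xi0_scale)
            return (0.0, 1.0, 1.0)

        def mu_fn(t):
            dmu, hf_s, _ = active_effect(t)
            return (m0 + dmu
                    + spec.a_lf * np.sin(2 * np.pi * spec.f_lf * t + ph_lf)
                    + spec.a_hf * hf_s * np.sin(2 * np.pi * spec.f_hf * t + ph_hf))

        def sh_fn(t):
            return xi0_s * active_effect(t)[2]

        sub_seed = int(rng.integers(0, 2**31 - 1))
        events = simulate_renewal(mu_fn, sh_fn, total, seed=sub_seed)
        recordings.append(SubjectRecording(subject_id=sid, events=events,
                                           annotations=tuple(anns)))
    return recordings


# ---------------------------------------------------------------------------
# chaotic surrogates and template ECG


_KNOWN_EXPONENTS = {"logistic": np.log(2.0), "henon": 0.419}


def simulate_chaotic_rr(map_name: str = "logistic", params: dict | None = None,
                        n: int = 1000, offset_seconds: float = 0.8,
                        scale: float = 0.1, seed: int = 0
                        ) -> tuple[np.ndarray, float]:
    """Chaotic-map pseudo-R-R intervals with the map's known dominant exponent.

    States are affinely mapped to ``offset + scale * state`` (states of the
    logistic map lie in (0,1), of the Henon map in roughly (-1.3, 1.3)); the
    result must be positive.  Returns (intervals, lambda1 in nats/iteration).
    """
    if n < 100:
        raise ValueError("n must be at least 100")
    rng = np.random.default_rng(seed)
    if map_name == "logistic":
        r = (params or {}).get("r", 4.0)
        x = rng.uniform(0.1, 0.9)
        states = np.empty(n)
        for i in range(n):
            x = r * x * (1.0 - x)
            states[i] = x
    elif map_name == "henon":
        a = (params or {}).get("a", 1.4)
        b = (params or {}).get("b", 0.3)
        x, y = rng.uniform(-0.1, 0.1, size=2)
        states = np.empty(n)
        for i in range(n + 100):
            x, y = 1.0 - a * x * x + y, b * x
            if i >= 100:
                states[i - 100] = x
    else:
        raise ValueError(f"unknown map {map_name!r}")
    rr = offset_seconds + scale * states
    if np.any(rr <= 0):
        raise ValueError("offset/scale imply non-positive intervals")
    return rr, _KNOWN_EXPONENTS[map_name]


def synthesize_ecg(beat_times, sampling_rate: float = 500.0,
                   snr_db: float | None = None, seed: int = 0,
                   duration: float | None = None):
    """Template-pulse ECG with R waves at the given times.

    A biphasic QRS template (sharp raised-cosine R with small Q/S dips) is
    placed at each beat time; optional additive white noise at the requested
    SNR.  Returns an :class:`~pphrv.rr_io.EcgTrace`.
    """
    from .rr_io import EcgTrace

    beat_times = np.asarray(beat_times, dtype=float)
    fs = sampling_rate
    if duration is None:
        duration = (beat_times[-1] if beat_times.size else 0.0) + 1.0
    n = int(round(duration * fs))
    x = np.zeros(n)
    half = int(round(0.012 * fs))  # ~24 ms R wave
    tt = np.arange(-half, half + 1) / fs
    r_wave = np.cos(np.pi * tt / (2 * half / fs)) ** 2
    s_off = int(round(0.030 * fs))
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > n:
            continue
        x[lo:hi] += r_wave
        for qo in (-s_off, s_off):  # Q and S dips
            qc = c + qo
            qlo, qhi = qc - half // 2, qc + half // 2 + 1
            if 0 <= qlo and qhi <= n:
                x[qlo:qhi] -= 0.15 * r_wave[::2][: qhi - qlo]
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        p_sig = np.mean(x**2)
        p_noise = p_sig / 10 ** (snr_db / 10.0)
        x = x + rng.standard_normal(n) * np.sqrt(p_noise)
    return EcgTrace(samples=x, sampling_rate=fs)
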