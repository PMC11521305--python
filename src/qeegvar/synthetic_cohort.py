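"""Synthetic multi-laboratory EEG studies.

Two levels of synthesis are provided.

``simulate_endpoint_table`` draws endpoint values directly from the
cross-laboratory generative model (fixed group effect plus Gaussian lab,
lab-by-group and residual terms), for testing the variance-component
estimator against known truth.

``synthesize_eeg``/``simulate_study`` generate full EEG waveforms per
laboratory profile: a 1/f^alpha background plus band-limited theta and
gamma oscillatory components, scaled in closed form on the FFT grid so the
realised band-power fractions hit their targets exactly before any
pipeline processing; lab gain and surgeon quality multiply the signal;
sensor white noise and Poisson-placed biphasic movement artifacts are
added on top.  Group effects act multiplicatively on band-power targets
(e.g. reduced total power and elevated relative theta in the transgenic
group; a dose-dependent post-dose gamma increase in the cross-over
design).  Everything is deterministic given the design and its seed.

The shipped phase templates mirror the three study stages: heterogeneous
gains, rates and analysis dialects ("localisation"), common parameters
with an optional poor-signal-quality lab ("harmonisation"), and a
vehicle/0.05/0.2 mg/kg cross-over with dose events ("ringtest").
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edf_io import Recording, write_metadata, write_recording
from .errors import ConfigError

__all__ = [
    "AnalysisDialect",
    "LabProfile",
    "SpectralTarget",
    "StudyDesign",
    "simulate_endpoint_table",
    "synthesize_eeg",
    "simulate_study",
    "load_template",
    "design_from_template",
]

THETA_BAND = (4.0, 8.0)
GAMMA_BAND = (32.0, 48.0)
#: Components carry power from 0.5 Hz (so the 0.5-48 Hz analysis dialect is
#: meaningful) up to 48 Hz ...
CONTENT_BAND = (0.5, 48.0)
#: ... but the power budget and band fractions are defined over the
#: measured total-power range, so pipeline endpoints land on target.
TOTAL_BAND = (1.0, 48.0)


@dataclass
class AnalysisDialect:
    """Per-laboratory analysis parameter overrides (local-analysis mode).

    ``report_scale`` captures the units each site reports relative power
    in (1 for a fraction, 100 for a percentage) — the kind of silent
    convention difference that makes locally analysed endpoints differ by
    orders of magnitude across laboratories.
    """

    total_range: tuple[float, float] = (1.0, 48.0)
    gamma_band: tuple[float, float] = (32.0, 48.0)
    theta_band: tuple[float, float] = (4.0, 8.0)
    artifact_multiplier: float = 6.0
    epoch_s: float = 10.0
    report_scale: float = 1.0


@dataclass
class LabProfile:
    """Acquisition characteristics of one laboratory.

    ``gain`` is the multiplicative amplitude factor of the recording chain
    (heterogeneous hardware spans orders of magnitude); ``surgeon_quality``
    in (0, 1] scales the structured signal relative to the sensor noise
    floor, emulating degraded implants; ``artifact_rate`` is movement
    artifacts per hour with amplitude ``artifact_amplitude`` times the
    running signal RMS.
    """

    lab_id: str
    gain: float = 1.0
    native_rate: float = 250.0
    noise_floor: float = 1.0  # microvolts RMS of sensor white noise
    artifact_rate: float = 20.0  # events per hour
    artifact_amplitude: float = 8.0  # multiples of running signal RMS
    surgeon_quality: float = 1.0
    dialect: AnalysisDialect = field(default_factory=AnalysisDialect)

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigError("gain must be positive")
        if self.native_rate < 100:
            raise ConfigError("native_rate must be at least 100 Hz")
        if self.artifact_rate < 0:
            raise ConfigError("artifact_rate must be non-negative")


@dataclass
class SpectralTarget:
    """Target spectral composition of the synthesized EEG.

    Fractions are of total power in the 0.5-48 Hz signal band: a theta
    bump (band-limited Gaussian profile) and a gamma bump over a 1/f^alpha
    background.  ``rms_uV`` sets the pre-gain amplitude scale.
    """

    theta_fraction: float = 0.30
    gamma_fraction: float = 0.06
    alpha: float = 2.0
    theta_centre: float = 7.0
    theta_width: float = 1.2
    gamma_centre: float = 40.0
    gamma_width: float = 4.0
    rms_uV: float = 50.0

    def __post_init__(self) -> None:
        if self.theta_fraction < 0 or self.gamma_fraction < 0:
            raise ConfigError("band fractions must be non-negative")
        if self.theta_fraction + self.gamma_fraction > 1:
            raise ConfigError("band fractions must sum to at most 1")


@dataclass
class StudyDesign:
    """A complete multi-laboratory study specification."""

    phase: str  # localisation | harmonisation | ringtest
    labs: list[LabProfile]
    groups: list[str]
    n_per_group: int = 12
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    duration_s: float = 600.0
    dose_time_s: float | None = None
    spectral_target: SpectralTarget = field(default_factory=SpectralTarget)
    biological_power_log10_sd: float = 0.15
    theta_jitter_log10_sd: float = 0.05
    gamma_jitter_log10_sd: float = 0.1
    session_power_log10_sd: float = 0.05
    dose_response_log10_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be at least 2")
        if self.phase == "ringtest" and self.dose_time_s is None:
            raise ConfigError("ringtest designs need dose_time_s")
        for g, eff in self.effects.items():
            if any(v <= 0 for v in eff.values()):
                raise ConfigError(f"effects for group {g!r} must be positive")

    @property
    def crossover(self) -> bool:
        """Ring-testing doses every animal with every group (cross-over)."""
        return self.phase == "ringtest"


# ---------------------------------------------------------------------------
# Endpoint-level generative model


def simulate_endpoint_table(
    n_labs: int,
    n_per_group: int,
    beta0: float,
    beta_d: float | dict[str, float],
    sigma_b2: float,
    sigma_d2: float,
    sigma_e2: float,
    seed: int,
    groups: tuple[str, ...] = ("WT", "TG"),
    endpoint: str = "simulated",
) -> tuple[pd.DataFrame, dict]:
    """Draw an endpoint table from the cross-laboratory generative model.

    Y_idl = beta0 + beta_d[group] + b_l + d_dl + eps_idl with centred
    normal b, d, eps of the stated variances.  Returns the table and a
    truth record of every parameter.  Deterministic under ``seed``.
    """
    if min(sigma_b2, sigma_d2, sigma_e2) < 0:
        raise ConfigError("variances must be non-negative")
    if np.isscalar(beta_d):
        beta_map = {g: (0.0 if i == 0 else float(beta_d)) for i, g in enumerate(groups)}
    else:
        beta_map = {groups[0]: 0.0, **{g: float(v) for g, v in beta_d.items()}}
    rng = np.random.default_rng(seed)
    rows = []
    for l in range(n_labs):
        lab = f"Lab{l + 1}"
        b_l = rng.normal(0.0, np.sqrt(sigma_b2))
        for g in groups:
            d_dl = rng.normal(0.0, np.sqrt(sigma_d2))
            eps = rng.normal(0.0, np.sqrt(sigma_e2), size=n_per_group)
            for i in range(n_per_group):
                rows.append(
                    {
                        "lab_id": lab,
                        "subject_id": f"{lab}_{g}_{i + 1}",
                        "group": g,
                        "endpoint": endpoint,
                        "value": beta0 + beta_map[g] + b_l + d_dl + eps[i],
                    }
                )
    truth = {
        "beta0": beta0,
        "beta_d": beta_map,
        "sigma_b2": sigma_b2,
        "sigma_d2": sigma_d2,
        "sigma_e2": sigma_e2,
        "n_labs": n_labs,
        "n_per_group": n_per_group,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Waveform synthesis


def _shaped_noise(rng, n: int, rate: float, gain_fn) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ``gain_fn(f)`` (unit scale)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = gain_fn(freqs)
    spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    return np.fft.irfft(spec, n=n)


def _band_power_fractions(x: np.ndarray, rate: float) -> dict[str, float]:
    """Periodogram power of ``x`` in the signal/theta/gamma bands (abs units)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    out = {}
    for name, (lo, hi) in [
        ("signal", TOTAL_BAND),
        ("theta", THETA_BAND),
        ("gamma", GAMMA_BAND),
    ]:
        m = (freqs >= lo) & (freqs < hi)
        out[name] = float(spec[m].sum()) * 2.0 / len(x) ** 2
    return out


def _synth_stationary(
    rng,
    n: int,
    rate: float,
    target: SpectralTarget,
    theta_mult: float,
    gamma_mult: float,
    total_ms: float,
) -> np.ndarray:
    """One stationary chunk whose realised band fractions hit the targets.

    Three independent shaped-noise components (background, theta bump,
    gamma bump) are mixed; the three squared scalings solve a linear
    system so that realised total power and theta/gamma band powers equal
    the (effect-adjusted) targets exactly on the FFT grid.
    """
    tau = min(target.theta_fraction * theta_mult, 0.95)
    gam = min(target.gamma_fraction * gamma_mult, 0.95)
    if tau + gam >= 1.0:
        raise ConfigError("adjusted band fractions exceed total power")

    def bg_gain(f):
        g = np.zeros_like(f)
        m = (f >= CONTENT_BAND[0]) & (f < CONTENT_BAND[1])
        g[m] = np.maximum(f[m], 1.0) ** (-target.alpha / 2.0)
        return g

    def bump(centre, width):
        def gain(f):
            g = np.exp(-0.5 * ((f - centre) / width) ** 2)
            g[(f < CONTENT_BAND[0]) | (f >= CONTENT_BAND[1])] = 0.0
            return g

        return gain

    comps = [
        _shaped_noise(rng, n, rate, bg_gain),
        _shaped_noise(rng, n, rate, bump(target.theta_centre, target.theta_width)),
        _shaped_noise(rng, n, rate, bump(target.gamma_centre, target.gamma_width)),
    ]
    P = np.array(
        [
            [f["signal"], f["theta"], f["gamma"]]
            for f in (_band_power_fractions(c, rate) for c in comps)
        ]
    ).T  # rows: signal/theta/gamma sums, cols: components
    b = total_ms * np.array([1.0, tau, gam])
    s2 = np.linalg.solve(P, b)
    if np.any(s2 < -1e-9 * total_ms):
        raise ConfigError(
            "unreachable spectral target: background band content already "
            "exceeds a requested band fraction"
        )
    s = np.sqrt(np.maximum(s2, 0.0))
    return s[0] * comps[0] + s[1] * comps[1] + s[2] * comps[2]


def _biphasic(n: int) -> np.ndarray:
    """One-cycle biphasic transient (positive then negative lobe)."""
    return np.sin(2 * np.pi * np.arange(n) / n)


def synthesize_eeg(
    profile: LabProfile,
    subject_id: str,
    group: str,
    target: SpectralTarget,
    duration_s: float,
    effects: dict[str, float] | None = None,
    dose_time_s: float | None = None,
    dose_label: str | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Recording, dict]:
    """Synthesize one recording for (laboratory profile, subject, group).

    ``effects`` maps {"total", "theta", "gamma"} to multiplicative
    band-power effects.  For dosed sessions (``dose_time_s`` set) the
    gamma effect applies only after the dose; total/theta effects apply
    throughout.  Returns the recording and a ground-truth dict (artifact
    intervals, realised targets) for detector-sensitivity tests.
    """
    if duration_s < 120:
        raise ConfigError("synthesized recordings must be at least 120 s")
    rate = profile.native_rate
    eff = {"total": 1.0, "theta": 1.0, "gamma": 1.0, **(effects or {})}
    rng = np.random.default_rng(seed)
    total_ms = target.rms_uV**2 * eff["total"]

    if dose_time_s is None:
        chunks = [(duration_s, eff["gamma"])]
    else:
        if not 0 < dose_time_s < duration_s:
            raise ConfigError("dose_time_s must fall inside the recording")
        gamma_pre = eff.get("gamma_pre", 1.0)
        chunks = [(dose_time_s, gamma_pre), (duration_s - dose_time_s, eff["gamma"])]

    parts = []
    for chunk_s, gamma_mult in chunks:
        n = int(round(chunk_s * rate))
        parts.append(
            _synth_stationary(rng, n, rate, target, eff["theta"], gamma_mult, total_ms)
        )
    x = np.concatenate(parts)
    x = profile.gain * profile.surgeon_quality * x
    x = x + profile.noise_floor * rng.standard_normal(len(x))

    clean_rms = float(np.sqrt(np.mean(x**2)))
    n_art = rng.poisson(profile.artifact_rate * duration_s / 3600.0)
    artifacts = []
    for _ in range(n_art):
        dur = rng.uniform(0.2, 1.0)
        t0 = rng.uniform(0.0, duration_s - dur)
        i0 = int(t0 * rate)
        m = int(dur * rate)
        x[i0 : i0 + m] += profile.artifact_amplitude * clean_rms * _biphasic(m)
        artifacts.append((float(t0), float(t0 + dur)))
    artifacts.sort()

    dose_events = []
    if dose_time_s is not None:
        dose_events = [(float(dose_time_s), dose_label or group)]
    rec = Recording(
        lab_id=profile.lab_id,
        subject_id=subject_id,
        group=group,
        samples=x,
        sampling_rate=rate,
        dose_events=dose_events,
    )
    truth = {
        "artifacts": artifacts,
        "clean_rms_uV": clean_rms,
        "total_ms": total_ms,
        "theta_fraction": min(target.theta_fraction * eff["theta"], 0.95),
        "gamma_fraction": target.gamma_fraction,
        "effects": eff,
    }
    return rec, truth


# ---------------------------------------------------------------------------
# Whole-study synthesis


def _subject_traits(design: StudyDesign, lab_i: int, subj_key: int):
    """Stable per-subject biology: power level and theta-fraction jitter.

    In the cross-over phase the key identifies the animal across its dose
    sessions (traits persist within subject); in the genotype phases each
    (group, index) pair is a distinct animal.
    """
    ss = np.random.SeedSequence([design.seed, 101, lab_i, subj_key])
    rng = np.random.default_rng(ss)
    power_mult = 10.0 ** rng.normal(0.0, design.biological_power_log10_sd)
    theta_mult = 10.0 ** rng.normal(0.0, design.theta_jitter_log10_sd)
    gamma_mult = 10.0 ** rng.normal(0.0, design.gamma_jitter_log10_sd)
    return power_mult, theta_mult, gamma_mult


def simulate_study(design: StudyDesign, out_dir) -> Path:
    """Write a complete synthetic study (EDF files, metadata, truth record).

    Genotype-style phases assign each subject to one group and one
    session; the cross-over phase records every subject once per dose,
    with the dose event stamped as an EDF+ annotation.  Per-recording
    seeds derive from the design seed, the lab, the subject and the
    session, so the study is reproducible file-for-file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truth: dict = {"design": _design_record(design), "recordings": {}}

    for lab_i, profile in enumerate(design.labs):
        if design.crossover:
            subjects = [f"m{j + 1}" for j in range(design.n_per_group)]
            sessions = [(s, g) for s in subjects for g in design.groups]
        else:
            sessions = []
            for g_i, g in enumerate(design.groups):
                sessions += [
                    (f"{g}{j + 1}", g) for j in range(design.n_per_group)
                ]
        for subj, group in sessions:
            subj_i = int("".join(c for c in subj if c.isdigit()) or 0)
            grp_i = design.groups.index(group)
            subj_key = subj_i if design.crossover else grp_i * 1000 + subj_i
            power_mult, theta_mult, gamma_subj = _subject_traits(
                design, lab_i, subj_key
            )
            sess_rng = np.random.default_rng(
                np.random.SeedSequence([design.seed, 202, lab_i, subj_i, grp_i])
            )
            session_mult = 10.0 ** sess_rng.normal(0.0, design.session_power_log10_sd)
            response_mult = 10.0 ** sess_rng.normal(0.0, design.dose_response_log10_sd)
            eff = dict(design.effects.get(group, {}))
            eff["total"] = eff.get("total", 1.0) * power_mult * session_mult
            eff["theta"] = eff.get("theta", 1.0) * theta_mult
            # the subject's own gamma level applies throughout; the dose
            # effect (plus session-level response variability) only after
            # the injection
            eff["gamma"] = eff.get("gamma", 1.0) * gamma_subj * response_mult
            if design.crossover:
                eff["gamma_pre"] = gamma_subj
            seed_seq = np.random.SeedSequence(
                [design.seed, 303, lab_i, subj_i, design.groups.index(group)]
            )
            rec, rec_truth = synthesize_eeg(
                profile,
                subj,
                group,
                design.spectral_target,
                duration_s=design.duration_s,
                effects=eff,
                dose_time_s=design.dose_time_s if design.crossover else None,
                dose_label=group if design.crossover else None,
                seed=seed_seq,
            )
            fname = f"{profile.lab_id}_{subj}_{group}.edf"
            write_recording(rec, out / fname)
            meta_rows.append(
                {
                    "lab_id": profile.lab_id,
                    "subject_id": subj,
                    "group": group,
                    "file": fname,
                    "phase": design.phase,
                    "channel": "EEG",
                }
            )
            truth["recordings"][fname] = rec_truth

    write_metadata(pd.DataFrame(meta_rows), out / "metadata.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return out


def _design_record(design: StudyDesign) -> dict:
    rec = asdict(design)
    return rec


# ---------------------------------------------------------------------------
# Phase templates


def load_template(name: str) -> dict:
    """Load a shipped phase template (localisation | harmonisation | ringtest)."""
    ref = resources.files("qeegvar").joinpath(f"templates/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigError(f"no template named {name!r}") from None
    return yaml.safe_load(text)


def design_from_template(name: str, seed: int, **overrides) -> StudyDesign:
    """Materialise a StudyDesign from a template.

    The template states distributions for lab heterogeneity (gain spread,
    native rates, dialect variants); this function draws the per-lab
    profiles deterministically from ``seed`` and applies any field
    overrides (e.g. ``n_per_group`` or ``duration_s``) on top.
    """
    tpl = load_template(name)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    n_labs = tpl["n_labs"]
    gain_sd = float(tpl.get("gain_log10_sd", 0.0))
    rates = tpl.get("native_rates", [250])
    dialects = tpl.get("dialects", [{}])
    qualities = tpl.get("surgeon_quality", [1.0] * n_labs)
    labs = []
    for i in range(n_labs):
        gain = 10.0 ** rng.normal(0.0, gain_sd)
        labs.append(
            LabProfile(
                lab_id=f"Lab{i + 1}",
                gain=gain,
                native_rate=float(rates[i % len(rates)]),
                noise_floor=float(tpl.get("noise_floor_uV", 1.0)),
                artifact_rate=float(tpl.get("artifact_rate_per_h", 20.0)),
                artifact_amplitude=float(tpl.get("artifact_amplitude", 8.0)),
                surgeon_quality=float(qualities[i % len(qualities)]),
                dialect=AnalysisDialect(**_tuplify(dialects[i % len(dialects)])),
            )
        )
    effects = {g: dict(e) for g, e in tpl.get("effects", {}).items()}
    design = StudyDesign(
        phase=tpl["phase"],
        labs=labs,
        groups=list(tpl["groups"]),
        n_per_group=int(tpl.get("n_per_group", 12)),
        effects=effects,
        duration_s=float(tpl.get("duration_s", 600.0)),
        dose_time_s=tpl.get("dose_time_s"),
        spectral_target=SpectralTarget(**tpl.get("spectral_target", {})),
        biological_power_log10_sd=float(tpl.get("biological_power_log10_sd", 0.15)),
        theta_jitter_log10_sd=float(tpl.get("theta_jitter_log10_sd", 0.05)),
        gamma_jitter_log10_sd=float(tpl.get("gamma_jitter_log10_sd", 0.1)),
        session_power_log10_sd=float(tpl.get("session_power_log10_sd", 0.05)),
        dose_response_log10_sd=float(tpl.get("dose_response_log10_sd", 0.05)),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(design, k, v)
    design.__post_init__()
    return design


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out
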