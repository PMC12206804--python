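"""Synthetic labeled EMG cohorts and impedance scenes.

No public recordings exist for chronically implanted epimysial and
intramuscular electrodes, so every downstream stage of the pipeline is
exercised on synthetic data with the statistical structure the analysis
assumes:

* each muscle source is band-limited Gaussian noise (20-250 Hz by default,
  clipped below Nyquist), normalized to unit RMS, and amplitude-modulated
  by a trapezoidal activation envelope (10% ramp at each end of a
  contraction) -- giving distinct transient and steady-state phases;
* electrodes observe a non-negative mixing of the sources; the diagonal
  dominance of the mixing matrix is the crosstalk knob (identity = perfect
  isolation).  Intramuscular electrodes are modelled with higher diagonal
  dominance (less crosstalk) than epimysial ones;
* i.i.d. Gaussian baseline noise per channel sets the rest-period floor;
* impedance scenes plant per-electrode direct and per-pair cross-channel
  values (ohms or OPEN) which the forward model turns into voltage
  measurements by Ohm's law -- direct paths around 10^2-10^3 ohms,
  cross-channel paths two or more orders of magnitude higher, with
  occasional open circuits on well-isolated pairs.

Cohort templates mirror a six-participant implant study: mixed-type
participants (4 epimysial + 8 intramuscular), epimysial-only (8, bipolar
or mixed polarity) and intramuscular-only (12) layouts, at sampling rates
of 500, 1000 or 2000 Hz.

All generators are deterministic: one master seed, with per-participant
and per-recording streams derived by fixed offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import signal as sps

from .impedance import OPEN, ImpedanceMeasurement, REF, is_open
from .io import Annotation, ElectrodeRecord, LabeledRecording, REST_LABEL

DEFAULT_CURRENT_AMP = {1000.0: 38.4e-9, 500.0: 19.2e-9}   # amperes
ALLOWED_RATES = (500, 1000, 2000)

#: off-diagonal mixing mass per electrode type (intramuscular = less crosstalk)
CROSSTALK_MASS = {"epimysial": 0.35, "intramuscular": 0.10}

#: planted impedance magnitudes (ohms): lognormal medians and sigmas per kind
SCENE_DISTRIBUTIONS = {
    ("direct", "epimysial"): (230.0, 0.5),
    ("direct", "intramuscular"): (2.0e3, 0.9),
    ("cross", "epimysial"): (4.2e3, 0.5),
    ("cross", "intramuscular"): (2.1e5, 1.0),
    ("cross", "mixed"): (3.0e4, 0.8),
}
#: probability that a cross-channel path is an open circuit, per pair kind
SCENE_OPEN_PROB = {"epimysial": 0.0, "intramuscular": 0.25, "mixed": 0.10}


# ---------------------------------------------------------------------------
# Protocol and mixing model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Movement:
    label: str
    group: str      # gross | finger

    def __post_init__(self):
        if self.group not in ("gross", "finger"):
            raise ValueError(f"unknown movement group {self.group!r}")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered movement list, repetition count and timing of a session."""

    movements: tuple
    repetitions_per_movement: int = 3
    contraction_duration_s: float = 2.0
    rest_duration_s: float = 1.0
    sampling_rate_hz: int = 500

    def __post_init__(self):
        object.__setattr__(self, "movements", tuple(self.movements))
        if self.repetitions_per_movement < 1:
            raise ValueError("need at least one repetition")
        if self.contraction_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_rate_hz not in ALLOWED_RATES:
            raise ValueError(
                f"sampling rate must be one of {ALLOWED_RATES}, "
                f"got {self.sampling_rate_hz}")
        if not self.movements:
            raise ValueError("protocol needs at least one movement")

    @property
    def movement_groups(self) -> dict[str, str]:
        return {m.label: m.group for m in self.movements}


@dataclass
class MixingModel:
    """Linear instantaneous electrode-to-source sensitivity model.

    Row i of ``mixing_matrix`` is electrode i's sensitivity to each muscle
    source; the diagonal dominance controls crosstalk.  ``activation_map``
    gives each movement's per-source activation gain in [0, 1].
    """

    mixing_matrix: np.ndarray
    activation_map: dict[str, np.ndarray]
    source_bandwidth_hz: tuple[float, float] = (20.0, 250.0)
    noise_rms: float = 0.05
    ramp_fraction: float = 0.1

    def __post_init__(self):
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        if self.mixing_matrix.ndim != 2:
            raise ValueError("mixing matrix must be channels x sources")
        if np.any(self.mixing_matrix < 0):
            raise ValueError("mixing matrix entries must be >= 0")
        if self.noise_rms < 0:
            raise ValueError("noise RMS must be >= 0")
        lo, hi = self.source_bandwidth_hz
        if not (0 < lo < hi):
            raise ValueError(f"bad source band ({lo}, {hi})")
        n_sources = self.mixing_matrix.shape[1]
        self.activation_map = {
            k: np.asarray(v, dtype=float) for k, v in self.activation_map.items()}
        for label, gains in self.activation_map.items():
            if gains.shape != (n_sources,):
                raise ValueError(
                    f"activation for {label!r} has {gains.size} gains for "
                    f"{n_sources} sources")
            if np.any(gains < 0) or np.any(gains > 1):
                raise ValueError(f"activation gains for {label!r} outside [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.mixing_matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.mixing_matrix.shape[1]


def crosstalk_mixing(n: int, offdiag_mass: float) -> np.ndarray:
    """n x n mixing matrix with diagonal 1-mass and the mass spread evenly
    over off-diagonal entries (mass 0 = perfect isolation)."""
    if not (0 <= offdiag_mass < 1):
        raise ValueError("off-diagonal mass must be in [0, 1)")
    if n == 1:
        return np.array([[1.0]])
    m = np.full((n, n), offdiag_mass / (n - 1))
    np.fill_diagonal(m, 1.0 - offdiag_mass)
    return m


def one_hot_activation(movements, n_sources: int,
                       gain: float = 1.0) -> dict[str, np.ndarray]:
    """Movement k activates source k mod n_sources only."""
    out = {}
    for k, mv in enumerate(movements):
        label = mv.label if isinstance(mv, Movement) else mv
        gains = np.zeros(n_sources)
        gains[k % n_sources] = gain
        out[label] = gains
    return out


def spread_activation(movements, n_sources: int) -> dict[str, np.ndarray]:
    """Movement k drives a primary muscle plus two weaker synergists.

    Primary source k mod n at gain 1.0, synergists at fixed offsets with
    gains 0.5 and 0.25 -- so every source sees activity within any run of
    a few movements, as muscles do across a movement protocol.
    """
    out = {}
    for k, mv in enumerate(movements):
        label = mv.label if isinstance(mv, Movement) else mv
        gains = np.zeros(n_sources)
        gains[k % n_sources] = 1.0
        if n_sources > 1:
            gains[(k + 5) % n_sources] = max(gains[(k + 5) % n_sources], 0.5)
            gains[(k + 9) % n_sources] = max(gains[(k + 9) % n_sources], 0.25)
        out[label] = gains
    return out


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

def _bandpass_sources(raw: np.ndarray, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)     # keep the upper edge below Nyquist
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, raw, axis=-1)
    rms = np.sqrt(np.mean(filtered ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return filtered / rms       # unit-RMS sources: planted SNR is analytic


def _trapezoid(n: int, ramp_fraction: float) -> np.ndarray:
    ramp = int(round(ramp_fraction * n))
    env = np.ones(n)
    if ramp > 0:
        up = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[:ramp] = up
        env[n - ramp:] = up[::-1]
    return env


def generate_recording(protocol: ProtocolSpec, mixing: MixingModel, seed: int,
                       electrode_records: list[ElectrodeRecord] | None = None,
                       channel_ids: list[str] | None = None) -> LabeledRecording:
    """Simulate one labeled session.

    The timeline interleaves rest with contractions, movement-major:
    rest, then for each movement each repetition followed by rest.  Equal
    seeds give bit-identical sample matrices.
    """
    fs = protocol.sampling_rate_hz
    missing = [m.label for m in protocol.movements
               if m.label not in mixing.activation_map]
    if missing:
        raise ValueError(f"activation map lacks movements {missing}")
    if electrode_records is not None and len(electrode_records) != mixing.n_channels:
        raise ValueError("electrode records disagree with mixing channel count")

    c_n = int(round(protocol.contraction_duration_s * fs))
    r_n = int(round(protocol.rest_duration_s * fs))
    if c_n < 1 or r_n < 1:
        raise ValueError("durations too short for the sampling rate")

    annotations: list[Annotation] = []
    cursor = 0

    def add(label: str, length: int, rep: int = 0):
        nonlocal cursor
        annotations.append(Annotation(start_s=cursor / fs,
                                      end_s=(cursor + length) / fs,
                                      label=label, repetition=rep))
        cursor += length

    add(REST_LABEL, r_n)
    for mv in protocol.movements:
        for rep in range(1, protocol.repetitions_per_movement + 1):
            add(mv.label, c_n, rep)
            add(REST_LABEL, r_n)
    n_total = cursor

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((mixing.n_sources, n_total))
    sources = _bandpass_sources(raw, fs, mixing.source_bandwidth_hz)

    envelope = np.zeros((mixing.n_sources, n_total))
    for ann in annotations:
        if ann.label == REST_LABEL:
            continue
        lo, hi = ann.sample_range(fs)
        env = _trapezoid(hi - lo, mixing.ramp_fraction)
        gains = mixing.activation_map[ann.label]
        envelope[:, lo:hi] = gains[:, None] * env[None, :]

    samples = mixing.mixing_matrix @ (sources * envelope)
    if mixing.noise_rms > 0:
        samples = samples + mixing.noise_rms * rng.standard_normal(samples.shape)

    if channel_ids is None:
        if electrode_records is not None:
            channel_ids = [e.electrode_id for e in electrode_records]
        else:
            channel_ids = [f"CH{i + 1:02d}" for i in range(mixing.n_channels)]
    return LabeledRecording(
        samples=samples,
        sampling_rate_hz=fs,
        channel_map=channel_ids,
        annotations=annotations,
        electrode_records=list(electrode_records or []),
        movement_groups=protocol.movement_groups,
    )


# ---------------------------------------------------------------------------
# Impedance scenes
# ---------------------------------------------------------------------------

@dataclass
class ImpedanceScene:
    """Planted impedances: per-electrode direct and per-pair cross values.

    Cross-channel values are independent planted parameters, not the
    solution of a resistive network -- the analysis consumes pairwise
    Ohm's-law readings only.
    """

    direct_ohm: dict = field(default_factory=dict)
    cross_ohm: dict = field(default_factory=dict)
    frequencies_hz: tuple = (1000.0, 500.0)
    current_amp: dict = field(default_factory=lambda: dict(DEFAULT_CURRENT_AMP))

    def __post_init__(self):
        self.cross_ohm = {tuple(sorted(k)): v for k, v in self.cross_ohm.items()}
        for v in list(self.direct_ohm.values()) + list(self.cross_ohm.values()):
            if not is_open(v) and not v > 0:
                raise ValueError(f"finite impedance must be positive, got {v}")
        for f in self.frequencies_hz:
            if f not in self.current_amp:
                raise ValueError(f"no test-current amplitude for {f} Hz")

    @property
    def electrodes(self) -> list[str]:
        ids = set(self.direct_ohm)
        for a, b in self.cross_ohm:
            ids.update((a, b))
        return sorted(ids)


def generate_impedance_measurements(scene: ImpedanceScene, noise_rel: float,
                                    seed: int,
                                    participant: str | None = None
                                    ) -> list[ImpedanceMeasurement]:
    """Forward Ohm's-law model: one measurement per frequency per connector pair.

    Voltage amplitude = Z * I * (1 + noise_rel * eps), eps ~ N(0, 1); OPEN
    entries emit measurements with the open flag set and zero voltage.
    """
    if noise_rel < 0:
        raise ValueError("relative noise must be >= 0")
    if not scene.direct_ohm and not scene.cross_ohm:
        raise ValueError("empty impedance scene")
    rng = np.random.default_rng(seed)
    out: list[ImpedanceMeasurement] = []
    for f in scene.frequencies_hz:
        current = scene.current_amp[f]
        pairs = [((e, REF), scene.direct_ohm[e]) for e in sorted(scene.direct_ohm)]
        pairs += [(p, scene.cross_ohm[p]) for p in sorted(scene.cross_ohm)]
        for (a, b), z in pairs:
            if is_open(z):
                out.append(ImpedanceMeasurement(
                    frequency_hz=f, connector_a=a, connector_b=b,
                    current_amp_A=current, voltage_amp_V=0.0,
                    open_flag=True, participant=participant))
            else:
                mult = 1.0 + noise_rel * rng.standard_normal() if noise_rel else 1.0
                out.append(ImpedanceMeasurement(
                    frequency_hz=f, connector_a=a, connector_b=b,
                    current_amp_A=current,
                    voltage_amp_V=max(z * current * mult, 0.0),
                    open_flag=False, participant=participant))
    return out


def make_crosstalk_scene(electrode_ids, offdiag_mass: float,
                         direct_ohm: float = 500.0) -> ImpedanceScene:
    """Scene whose cross/direct ratio is driven by the crosstalk knob.

    Cross-channel impedance scales inversely with the off-diagonal mixing
    mass (strong crosstalk = low-resistance inter-electrode path); zero
    mass plants OPEN circuits.
    """
    ids = list(electrode_ids)
    direct = {e: direct_ohm for e in ids}
    cross = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if offdiag_mass <= 0:
                cross[(a, b)] = OPEN
            else:
                cross[(a, b)] = direct_ohm / offdiag_mass
    return ImpedanceScene(direct_ohm=direct, cross_ohm=cross)


def sample_scene(electrode_records: list[ElectrodeRecord],
                 seed: int) -> ImpedanceScene:
    """Plant a realistic impedance scene for an electrode layout.

    Direct paths are lognormal around a few hundred ohms (epimysial) or a
    couple of kilo-ohms (intramuscular); cross-channel paths sit two or
    more orders of magnitude higher, with open circuits most likely
    between well-isolated intramuscular pairs.
    """
    rng = np.random.default_rng(seed)
    direct, cross = {}, {}
    for e in electrode_records:
        med, sigma = SCENE_DISTRIBUTIONS[("direct", e.etype)]
        direct[e.electrode_id] = float(np.exp(np.log(med) + sigma * rng.standard_normal()))
    for i, a in enumerate(electrode_records):
        for b in electrode_records[i + 1:]:
            kind = a.etype if a.etype == b.etype else "mixed"
            if rng.random() < SCENE_OPEN_PROB[kind]:
                cross[(a.electrode_id, b.electrode_id)] = OPEN
            else:
                med, sigma = SCENE_DISTRIBUTIONS[("cross", kind)]
                cross[(a.electrode_id, b.electrode_id)] = float(
                    np.exp(np.log(med) + sigma * rng.standard_normal()))
    return ImpedanceScene(direct_ohm=direct, cross_ohm=cross)


# ---------------------------------------------------------------------------
# Cohort templates
# ---------------------------------------------------------------------------

GROSS_MOVEMENTS = ("open_hand", "close_hand", "flex_wrist", "extend_wrist",
                   "pronate_wrist", "supinate_wrist")
ELBOW_MOVEMENTS = ("flex_elbow", "extend_elbow")     # trans-humeral only
FINGER_MOVEMENTS = tuple(f"{act}_{digit}" for digit in
                         ("thumb", "index", "middle", "ring", "little")
                         for act in ("flex", "extend"))


@dataclass
class CohortEntry:
    """One synthetic participant: session recording, impedance log, metadata."""

    participant: str
    recording: LabeledRecording
    measurements: list[ImpedanceMeasurement]
    electrode_map: list[ElectrodeRecord]
    scene: ImpedanceScene


def load_templates() -> dict:
    """The packaged cohort-template registry (JSON)."""
    text = resources.files("iemg").joinpath("cohort_templates.json").read_text()
    return json.loads(text)["templates"]


def template_protocol(template: dict,
                      repetitions: int = 3,
                      contraction_s: float = 2.0,
                      rest_s: float = 1.0) -> ProtocolSpec:
    gross = GROSS_MOVEMENTS + (ELBOW_MOVEMENTS
                               if template["amputation_level"] == "TH" else ())
    movements = tuple(Movement(m, "gross") for m in gross)
    movements += tuple(Movement(m, "finger") for m in FINGER_MOVEMENTS)
    return ProtocolSpec(movements=movements,
                        repetitions_per_movement=repetitions,
                        contraction_duration_s=contraction_s,
                        rest_duration_s=rest_s,
                        sampling_rate_hz=template["sampling_rate_hz"])


def template_mixing(template: dict, protocol: ProtocolSpec,
                    noise_rms: float = 0.05) -> MixingModel:
    """Mixing model for a template: one source per electrode, per-row
    crosstalk set by the electrode's type, one-hot movement activation."""
    electrodes = template["electrodes"]
    n = len(electrodes)
    m = np.zeros((n, n))
    for i, e in enumerate(electrodes):
        mass = CROSSTALK_MASS[e["etype"]]
        row = np.full(n, mass / (n - 1)) if n > 1 else np.array([0.0])
        row[i] = 1.0 - mass
        m[i] = row
    activation = spread_activation(protocol.movements, n)
    return MixingModel(mixing_matrix=m, activation_map=activation,
                       noise_rms=noise_rms)


def _electrode_records(template: dict) -> list[ElectrodeRecord]:
    return [ElectrodeRecord(electrode_id=e["id"], etype=e["etype"],
                            polarity=e["polarity"],
                            target_muscle=e["target_muscle"],
                            neuromuscular_construct=e["construct"])
            for e in template["electrodes"]]


def _derived_seed(master: int, *key: int) -> int:
    """Fixed-offset child seed, kept below 2**31."""
    state = np.random.SeedSequence([int(master) % (2 ** 31), *key]).generate_state(1)
    return int(state[0] % (2 ** 31))


def generate_cohort(template_name: str, seed: int,
                    repetitions: int = 3,
                    contraction_s: float = 2.0,
                    rest_s: float = 1.0,
                    noise_rms: float = 0.05,
                    impedance_noise_rel: float = 0.02
                    ) -> dict[str, CohortEntry]:
    """Generate the named template's participant(s) from one master seed.

    ``template_name`` is a registry key (e.g. ``"TR1-like"``) or ``"all"``
    for the full six-participant cohort.  Per-participant streams are
    derived from the master seed by fixed offsets, so cohorts are
    reproducible element-wise.
    """
    registry = load_templates()
    if template_name == "all":
        names = sorted(registry)
    elif template_name in registry:
        names = [template_name]
    else:
        raise KeyError(f"unknown cohort template {template_name!r}; "
                       f"available: {sorted(registry)} or 'all'")
    cohort: dict[str, CohortEntry] = {}
    for idx, name in enumerate(sorted(names)):
        template = registry[name]
        protocol = template_protocol(template, repetitions, contraction_s, rest_s)
        mixing = template_mixing(template, protocol, noise_rms)
        records = _electrode_records(template)
        rec_seed = _derived_seed(seed, idx, 0)
        scene_seed = _derived_seed(seed, idx, 1)
        meas_seed = _derived_seed(seed, idx, 2)
        recording = generate_recording(protocol, mixing, rec_seed,
                                       electrode_records=records)
        scene = sample_scene(records, scene_seed)
        measurements = generate_impedance_measurements(
            scene, impedance_noise_rel, meas_seed, participant=name)
        cohort[name] = CohortEntry(participant=name, recording=recording,
                                   measurements=measurements,
                                   electrode_map=records, scene=scene)
    return cohort
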