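"""Synthetic gas-sensor-array recordings for binary ethanol / n-propanol mixtures.

Emulates a concentration-gradient cycling protocol on an array of eight
cross-sensitive metal-oxide (MOS) sensors: each recording steps the
concentration of one or both gases through a schedule of 5-minute exposure /
5-minute recovery cycles sampled at 2 Hz.  The sensor signal is the response
ratio ``s = R0 / R`` (baseline resistance over in-gas resistance), which for
reducing gases rises above 1 on exposure.

The sensor model is phenomenological, not a surface-chemistry simulation:

* steady state      ``s_inf = 1 + a_e * C_e**b_e + a_p * C_p**b_p``
  (additive power-law response per gas; exactly 1 in clean air),
* dynamics          each gas contributes its own first-order component that
  relaxes toward its steady-state amplitude during exposure and back toward
  zero during recovery.  Time constants are gas-specific (per-gas kinetic
  multipliers on the sensor's base response/recovery times) and speed up
  with concentration, as adsorption kinetics do on MOS surfaces — so the
  *shape* of the rise, not only its amplitude, encodes composition and
  concentration (amplitude is deliberately discarded later by per-window
  min-max normalization),
* noise             multiplicative Gaussian on the response ratio,
* optional slow linear baseline drift (off by default).

Cross-sensitivity — the reason an array plus a model is needed at all — comes
from giving the eight sensors distinct sensitivity pairs, so that no single
channel separates the two gases.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: class-index convention used across the package (fixed, do not reorder):
#: 0 = single n-propanol ("01"), 1 = single ethanol ("10"), 2 = mixture ("11")
CLASS_NAMES = ("single_propanol", "single_ethanol", "mixture")
CLASS_CODES = ("01", "10", "11")

SAMPLE_RATE_HZ = 2.0
EXPOSURE_S = 300.0
RECOVERY_S = 300.0
LEAD_IN_S = 240.0  # air baseline before the first exposure


@dataclass(frozen=True)
class SensorModel:
    """One MOS sensor: power-law sensitivities and first-order dynamics."""

    sensor_id: str
    r0: float = 10_000.0            # baseline resistance in air, ohm
    a_ethanol: float = 0.1          # sensitivity amplitude per gas (>= 0)
    b_ethanol: float = 0.8          # power-law exponent, (0, 1.5]
    a_propanol: float = 0.1
    b_propanol: float = 0.8
    tau_on: float = 45.0            # base response time constant, s
    tau_off: float = 70.0           # base recovery time constant, s
    kin_ethanol: float = 1.0        # per-gas kinetic multiplier on tau_on/off
    kin_propanol: float = 2.0
    conc_speedup: float = 1.0       # fractional response-rate gain at 100 ppm
    noise_sd: float = 0.001         # relative (multiplicative) noise level

    def __post_init__(self):
        if self.r0 <= 0 or self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("r0 and time constants must be positive")
        if self.kin_ethanol <= 0 or self.kin_propanol <= 0:
            raise ValueError("kinetic multipliers must be positive")
        if self.conc_speedup < 0:
            raise ValueError("conc_speedup must be non-negative")
        if self.a_ethanol < 0 or self.a_propanol < 0 or self.noise_sd < 0:
            raise ValueError("sensitivities and noise_sd must be non-negative")
        for b in (self.b_ethanol, self.b_propanol):
            if not 0 < b <= 1.5:
                raise ValueError("exponents must lie in (0, 1.5]")

    def tau_response(self, gas: str, conc_ppm: float) -> float:
        """Exposure time constant for one gas at one concentration."""
        kin = self.kin_ethanol if gas == "ethanol" else self.kin_propanol
        return self.tau_on * kin / (1.0 + self.conc_speedup * conc_ppm / 100.0)

    def tau_recovery(self, gas: str) -> float:
        kin = self.kin_ethanol if gas == "ethanol" else self.kin_propanol
        return self.tau_off * kin


@dataclass(frozen=True)
class ExposureScheme:
    """One test scheme: an ordered schedule of (ethanol, propanol) ppm pairs."""

    scheme_id: str
    concentration_pairs: tuple[tuple[float, float], ...]
    exposure_s: float = EXPOSURE_S
    recovery_s: float = RECOVERY_S
    sample_rate_hz: float = SAMPLE_RATE_HZ
    lead_in_s: float = LEAD_IN_S

    def __post_init__(self):
        if len(self.concentration_pairs) == 0:
            raise ValueError("concentration schedule must not be empty")
        for eth, prop in self.concentration_pairs:
            if eth < 0 or prop < 0:
                raise ValueError("concentrations must be non-negative")

    @property
    def samples_per_cycle(self) -> int:
        return int(round((self.exposure_s + self.recovery_s) * self.sample_rate_hz))

    @property
    def n_samples(self) -> int:
        lead = int(round(self.lead_in_s * self.sample_rate_hz))
        return lead + len(self.concentration_pairs) * self.samples_per_cycle


@dataclass
class SensorArrayRecording:
    """One simulated experiment: time axis, 8 response channels, schedule."""

    time: np.ndarray                 # (T,) seconds
    response: np.ndarray             # (8, T) response-ratio units
    scheme_id: str
    schedule: list[dict]             # per cycle: ethanol/propanol ppm, start/end sample
    sensor_ids: list[str]
    sample_rate_hz: float
    repeat_index: int = 0
    seed: int = 0

    @property
    def n_sensors(self) -> int:
        return self.response.shape[0]


def classify_composition(ethanol_ppm: float, propanol_ppm: float) -> int | None:
    """Class index for a concentration pair; None for clean air."""
    if ethanol_ppm > 0 and propanol_ppm > 0:
        return 2
    if ethanol_ppm > 0:
        return 1
    if propanol_ppm > 0:
        return 0
    return None


def steady_state_response(model: SensorModel, conc: tuple[float, float]) -> float:
    """Steady-state response ratio at an (ethanol, propanol) ppm pair.

    Additive power-law per gas; exactly 1 at zero concentration and
    non-decreasing in each gas.
    """
    eth, prop = conc
    if eth < 0 or prop < 0:
        raise ValueError(f"negative concentration: ({eth}, {prop})")
    s = 1.0
    if eth > 0:
        s += model.a_ethanol * eth ** model.b_ethanol
    if prop > 0:
        s += model.a_propanol * prop ** model.b_propanol
    return s


def response_from_resistance(resistance: np.ndarray, r0: float) -> np.ndarray:
    """Convert a raw resistance trace to the response ratio s = R0 / R."""
    return np.asarray(r0, dtype=float) / np.asarray(resistance, dtype=float)


def default_sensor_bank() -> list[SensorModel]:
    """Eight cross-sensitive sensors with deliberately dissimilar parameters.

    Sensitivity pairs are spread over the (ethanol, propanol) plane so that
    the array as a whole is informative about both gases while no individual
    channel is; time constants differ so channels carry distinct dynamics.
    """
    spec = [
        # id,    r0,     a_eth, b_eth, a_prop, b_prop, t_on, t_off, kin_p, speedup
        ("mq2", 12_000.0, 0.08, 0.85, 0.20, 0.80, 45.0, 70.0, 2.2, 1.0),
        ("mq3", 25_000.0, 0.50, 0.90, 0.12, 0.75, 30.0, 50.0, 1.6, 1.2),
        ("mq4", 18_000.0, 0.06, 0.70, 0.05, 0.95, 60.0, 90.0, 2.4, 0.6),
        ("mq5", 30_000.0, 0.15, 0.80, 0.30, 0.85, 40.0, 65.0, 1.8, 1.0),
        ("mq6", 22_000.0, 0.10, 0.95, 0.40, 0.70, 55.0, 80.0, 2.0, 0.8),
        ("mq7", 15_000.0, 0.25, 0.75, 0.08, 0.90, 35.0, 60.0, 2.6, 1.1),
        ("mq8", 40_000.0, 0.04, 1.00, 0.15, 0.65, 70.0, 100.0, 1.7, 0.7),
        ("mq9", 20_000.0, 0.30, 0.65, 0.25, 1.00, 50.0, 75.0, 2.1, 0.9),
    ]
    return [
        SensorModel(sensor_id=i, r0=r0, a_ethanol=ae, b_ethanol=be,
                    a_propanol=ap, b_propanol=bp, tau_on=ton, tau_off=toff,
                    kin_propanol=kp, conc_speedup=cs)
        for i, r0, ae, be, ap, bp, ton, toff, kp, cs in spec
    ]


def default_schemes() -> list[ExposureScheme]:
    """The seven default test schemes G1–G7.

    G1 steps pure ethanol and G2 pure n-propanol through 20..100 ppm in
    20 ppm increments (the 0 ppm level is the initial air baseline, not a
    counted exposure).  G3–G7 hold one gas at a scheme-specific constant
    while the other steps 20..100 ppm, covering a grid of mixing ratios.
    """
    steps = [20.0, 40.0, 60.0, 80.0, 100.0]

    def pairs(fix_eth=None, fix_prop=None):
        if fix_eth is not None:
            return tuple((fix_eth, p) for p in steps)
        if fix_prop is not None:
            return tuple((e, fix_prop) for e in steps)
        raise AssertionError

    return [
        ExposureScheme("G1", tuple((e, 0.0) for e in steps)),
        ExposureScheme("G2", tuple((0.0, p) for p in steps)),
        ExposureScheme("G3", pairs(fix_eth=20.0)),
        ExposureScheme("G4", pairs(fix_eth=60.0)),
        ExposureScheme("G5", pairs(fix_eth=100.0)),
        ExposureScheme("G6", pairs(fix_prop=40.0)),
        ExposureScheme("G7", pairs(fix_prop=80.0)),
    ]


def simulate_recording(
    scheme: ExposureScheme,
    bank: list[SensorModel],
    seed: int,
    repeat_index: int = 0,
    drift_per_hour: float = 0.0,
) -> SensorArrayRecording:
    """Simulate one recording: every concentration pair gets one exposure +
    recovery cycle; sensors relax exponentially toward the steady state
    during exposure and toward baseline during recovery.

    Deterministic given (scheme, bank, seed).  `drift_per_hour` adds a slow
    linear baseline drift (fraction of baseline per hour, default off).
    """
    if len(scheme.concentration_pairs) == 0:
        raise ValueError("empty concentration schedule")
    fs = scheme.sample_rate_hz
    dt = 1.0 / fs
    n_exp = int(round(scheme.exposure_s * fs))
    n_rec = int(round(scheme.recovery_s * fs))
    n_lead = int(round(scheme.lead_in_s * fs))
    n_total = scheme.n_samples
    time = np.arange(n_total) * dt

    rng = np.random.default_rng(seed)
    response = np.empty((len(bank), n_total))
    schedule: list[dict] = []

    for c, (eth, prop) in enumerate(scheme.concentration_pairs):
        start = n_lead + c * (n_exp + n_rec)
        schedule.append({
            "ethanol_ppm": float(eth),
            "propanol_ppm": float(prop),
            "start_sample": int(start),
            "end_sample": int(start + n_exp + n_rec),
            "peak_sample_nominal": int(start + n_exp - 1),
        })

    t_exp = np.arange(1, n_exp + 1) * dt
    t_rec = np.arange(1, n_rec + 1) * dt
    for si, sensor in enumerate(bank):
        y = np.zeros(n_total)  # excess response above the air baseline of 1
        # each gas keeps its own first-order component across cycles, so
        # incomplete recovery carries over and the rise shape is a
        # composition-dependent mix of two exponentials
        comp = {"ethanol": 0.0, "propanol": 0.0}
        amp = {"ethanol": lambda c_: sensor.a_ethanol * c_ ** sensor.b_ethanol if c_ > 0 else 0.0,
               "propanol": lambda c_: sensor.a_propanol * c_ ** sensor.b_propanol if c_ > 0 else 0.0}
        for c, (eth, prop) in enumerate(scheme.concentration_pairs):
            if eth < 0 or prop < 0:
                raise ValueError(f"negative concentration: ({eth}, {prop})")
            start = n_lead + c * (n_exp + n_rec)
            conc = {"ethanol": eth, "propanol": prop}
            for gas in comp:
                target = amp[gas](conc[gas])
                tau = sensor.tau_response(gas, conc[gas])
                # exact solution of dx/dt = (target - x)/tau, constant target
                trace = target + (comp[gas] - target) * np.exp(-t_exp / tau)
                y[start:start + n_exp] += trace
                comp[gas] = trace[-1]
            for gas in comp:
                trace = comp[gas] * np.exp(-t_rec / sensor.tau_recovery(gas))
                y[start + n_exp:start + n_exp + n_rec] += trace
                comp[gas] = trace[-1]
        y += 1.0
        if drift_per_hour != 0.0:
            y = y + drift_per_hour * (time / 3600.0)
        if sensor.noise_sd > 0:
            y = y * (1.0 + sensor.noise_sd * rng.standard_normal(n_total))
        response[si] = y

    return SensorArrayRecording(
        time=time,
        response=response,
        scheme_id=scheme.scheme_id,
        schedule=schedule,
        sensor_ids=[s.sensor_id for s in bank],
        sample_rate_hz=fs,
        repeat_index=repeat_index,
        seed=seed,
    )


@dataclass(frozen=True)
class CampaignConfig:
    """A full measurement campaign: schemes x repeats."""

    schemes: tuple[ExposureScheme, ...] = field(default_factory=lambda: tuple(default_schemes()))
    repeats: int = 5
    noise_sd: float | None = None        # override every sensor's noise level
    drift_per_hour: float = 0.0
    label_by: str = "composition"        # or "scheme"

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.label_by not in ("composition", "scheme"):
            raise ValueError("label_by must be 'composition' or 'scheme'")

    @property
    def n_responses(self) -> int:
        return sum(len(s.concentration_pairs) for s in self.schemes) * self.repeats


def scheme_label(scheme_id: str) -> int:
    """Scheme-level class label: G1 -> single ethanol, G2 -> single propanol,
    everything else -> mixture."""
    if scheme_id == "G1":
        return 1
    if scheme_id == "G2":
        return 0
    return 2


def cycle_labels(scheme: ExposureScheme, label_by: str = "composition") -> list[int | None]:
    """Class index per cycle of a scheme (None = clean-air cycle, unlabeled)."""
    if label_by == "scheme":
        return [scheme_label(scheme.scheme_id)] * len(scheme.concentration_pairs)
    return [classify_composition(e, p) for e, p in scheme.concentration_pairs]


def generate_campaign(
    config: CampaignConfig,
    seed: int,
    bank: list[SensorModel] | None = None,
) -> list[SensorArrayRecording]:
    """Simulate all recordings of a campaign, deterministically from `seed`.

    With the defaults (7 schemes x 5 cycles x 5 repeats) the campaign holds
    175 individually labeled sensor-array responses in 35 recordings.
    """
    bank = list(default_sensor_bank()) if bank is None else bank
    if config.noise_sd is not None:
        bank = [dataclasses.replace(s, noise_sd=config.noise_sd) for s in bank]
    recordings = []
    idx = 0
    for rep in range(config.repeats):
        for scheme in config.schemes:
            rng_seed = int(np.random.default_rng([int(seed), idx]).integers(2 ** 31))
            recordings.append(
                simulate_recording(scheme, bank, seed=rng_seed, repeat_index=rep,
                                   drift_per_hour=config.drift_per_hour)
            )
            idx += 1
    total = sum(len(r.schedule) for r in recordings)
    logger.info("campaign: %d recordings, %d responses", len(recordings), total)
    return recordings


# -- disk round-trip -------------------------------------------------------

def write_recording(rec: SensorArrayRecording, directory: str | Path) -> Path:
    """Write one recording as CSV (time_s, s1..s8) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.scheme_id}_rep{rec.repeat_index}"
    cols = {"time_s": rec.time}
    for i in range(rec.n_sensors):
        cols[f"s{i + 1}"] = rec.response[i]
    pd.DataFrame(cols).to_csv(directory / f"{stem}.csv", index=False, float_format="%.8g")
    meta = {
        "scheme_id": rec.scheme_id,
        "repeat_index": rec.repeat_index,
        "seed": rec.seed,
        "sample_rate_hz": rec.sample_rate_hz,
        "sensor_ids": rec.sensor_ids,
        "schedule": rec.schedule,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return directory / f"{stem}.csv"


def read_recording(csv_path: str | Path) -> SensorArrayRecording:
    """Inverse of :func:`write_recording`."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    sensor_cols = [c for c in df.columns if c != "time_s"]
    return SensorArrayRecording(
        time=df["time_s"].to_numpy(),
        response=df[sensor_cols].to_numpy().T,
        scheme_id=meta["scheme_id"],
        schedule=meta["schedule"],
        sensor_ids=meta["sensor_ids"],
        sample_rate_hz=meta["sample_rate_hz"],
        repeat_index=meta["repeat_index"],
        seed=meta["seed"],
    )
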