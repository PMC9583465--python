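"""Forward extended-RIC (eRIC) respiratory impedance model and cohort simulation.

The eRIC circuit is a two-compartment electrical analog of the respiratory
system: a central resistance ``R`` in series with an inertance ``I`` and a
parallel block of peripheral resistance ``Rp`` and compliance ``C``.  Its
impedance at angular frequency ``w = 2*pi*f`` is

    Z(w) = R + Rp / (1 + (w*Rp*C)^2)
             + j * ( w*I - w*Rp^2*C / (1 + (w*Rp*C)^2) )

Units follow forced-oscillation convention: resistances in cmH2O.s/L,
inertance in cmH2O.s^2/L, compliance in L/cmH2O.

Because the clinical dataset that motivated this package is not public, the
module also provides a synthetic cohort generator: subjects are drawn from
group-specific log-normal parameter distributions (control, sarcoidosis with
normal spirometry, sarcoidosis with altered spirometry), each subject's
spectrum is measured in noisy replicates and averaged, mirroring the
three-measurement protocol of a routine oscillometry exam.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ERICParameters",
    "ImpedanceSpectrum",
    "GroupDistribution",
    "CohortConfig",
    "SubjectRecord",
    "DEFAULT_FREQUENCIES",
    "GROUP_CONTROL",
    "GROUP_NORMAL",
    "GROUP_ALTERED",
    "eric_impedance",
    "resonant_frequency_analytic",
    "simulate_cohort",
    "cohort_to_frames",
    "write_cohort",
    "read_cohort",
    "derive_seed",
]

#: Measurement grid of a standard exam: multiples of 2 Hz covering 4-32 Hz.
DEFAULT_FREQUENCIES: np.ndarray = np.arange(4.0, 33.0, 2.0)

GROUP_CONTROL = "control"
GROUP_NORMAL = "sarcoidosis_normal"
GROUP_ALTERED = "sarcoidosis_altered"


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a single global seed.

    Stages of a pipeline run can be re-executed in isolation and still see
    the stream they saw inside the full run.  The result is always in
    ``[0, 2**31)``.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ERICParameters:
    """eRIC circuit components.

    Attributes
    ----------
    R : float
        Central airway resistance, cmH2O.s/L.
    Rp : float
        Peripheral resistance, cmH2O.s/L.
    I : float
        Inertance, cmH2O.s^2/L.
    C : float
        Compliance, L/cmH2O.
    """

    R: float
    Rp: float
    I: float
    C: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError(f"central resistance R must be >= 0, got {self.R}")
        if self.Rp < 0:
            raise ValueError(f"peripheral resistance Rp must be >= 0, got {self.Rp}")
        if self.I < 0:
            raise ValueError(f"inertance I must be >= 0, got {self.I}")
        if self.C <= 0:
            raise ValueError(f"compliance C must be > 0, got {self.C}")

    @property
    def Rt(self) -> float:
        """Total resistance, the series sum R + Rp."""
        return self.R + self.Rp

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.Rp, self.I, self.C])


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex respiratory impedance tabulated on a frequency grid.

    ``resistance`` is the real part, ``reactance`` the imaginary part, both in
    cmH2O.s/L; ``frequencies`` in Hz, strictly increasing within [4, 32].
    """

    frequencies: np.ndarray
    resistance: np.ndarray
    reactance: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        r = np.asarray(self.resistance, dtype=float)
        x = np.asarray(self.reactance, dtype=float)
        if not (len(f) == len(r) == len(x)):
            raise ValueError(
                f"length mismatch: {len(f)} frequencies, {len(r)} resistance, "
                f"{len(x)} reactance values"
            )
        if len(f) and (np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be strictly increasing")
        if len(f) and f[0] <= 0:
            raise ValueError(f"frequencies must be positive, got {f[0]}")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "resistance", r)
        object.__setattr__(self, "reactance", x)

    @property
    def impedance(self) -> np.ndarray:
        """Complex impedance values."""
        return self.resistance + 1j * self.reactance

    def at(self, frequency: float) -> complex:
        """Exact grid lookup; raises if the frequency is not on the grid."""
        idx = np.flatnonzero(np.isclose(self.frequencies, frequency))
        if idx.size == 0:
            raise ValueError(f"frequency {frequency} Hz not on the measured grid")
        return complex(self.resistance[idx[0]], self.reactance[idx[0]])


def eric_impedance(params: ERICParameters, frequencies) -> ImpedanceSpectrum:
    """Evaluate the eRIC impedance on a frequency grid.

    Parameters
    ----------
    params : ERICParameters
        Circuit components.
    frequencies : array-like of float
        Frequencies in Hz, strictly positive.

    Returns
    -------
    ImpedanceSpectrum
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        bad = f[f <= 0][0]
        raise ValueError(f"frequencies must be positive, got {bad}")
    w = 2.0 * np.pi * f
    denom = 1.0 + (w * params.Rp * params.C) ** 2
    real = params.R + params.Rp / denom
    imag = w * params.I - w * params.Rp**2 * params.C / denom
    return ImpedanceSpectrum(frequencies=f, resistance=real, reactance=imag)


def resonant_frequency_analytic(params: ERICParameters) -> float | None:
    """Closed-form resonant frequency of the eRIC model, in Hz.

    The resonant frequency is where the reactance crosses zero (inertial and
    elastic contributions cancel).  Setting the imaginary part of the model
    to zero gives

        f_r = (1 / 2*pi) * sqrt( (Rp^2*C - I) / (I * Rp^2 * C^2) )

    which is real only when ``Rp^2*C > I`` (and ``I > 0``); otherwise the
    reactance never crosses zero and ``None`` is returned.
    """
    num = params.Rp**2 * params.C - params.I
    if params.I <= 0 or num <= 0:
        return None
    w_r = np.sqrt(num / (params.I * params.Rp**2 * params.C**2))
    return float(w_r / (2.0 * np.pi))


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------

#: Control-group median eRIC parameters, chosen as typical adult values.
_CONTROL_MEDIAN = {"R": 2.0, "Rp": 1.2, "I": 0.008, "C": 0.020}

#: Log-scale standard deviations (dimensionless, on ln parameter).
_CONTROL_SIGMA = {"R": 0.25, "Rp": 0.30, "I": 0.25, "C": 0.30}

#: Multiplicative median shifts per disease group.  Disease raises peripheral
#: resistance and lowers compliance (hence higher Rt, Fr, Ax, Z4 and lower
#: Cdyn), more strongly when spirometry is already altered.  Shift sizes are
#: calibrated once so the best univariate feature AUCs land near 0.80
#: (normal-spirometry analysis) and near 0.87 (altered), the regime the
#: emulated study reports.
_SHIFT_NORMAL = {"R": 1.10, "Rp": 1.40, "I": 1.05, "C": 0.75}
_SHIFT_ALTERED = {"R": 1.15, "Rp": 1.50, "I": 1.08, "C": 0.70}


@dataclass(frozen=True)
class GroupDistribution:
    """Log-normal distribution of eRIC parameters for one subject group.

    ``median`` maps each component name to the group's median value;
    ``sigma_log`` to the standard deviation of the natural log.
    """

    median: dict[str, float]
    sigma_log: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("R", "Rp", "I", "C"):
            if name not in self.median or name not in self.sigma_log:
                raise ValueError(f"distribution missing component {name!r}")
            if self.median[name] <= 0:
                raise ValueError(f"median of {name} must be > 0")
            if self.sigma_log[name] < 0:
                raise ValueError(f"dispersion of {name} must be >= 0")

    def draw(self, rng: np.random.Generator) -> ERICParameters:
        vals = {
            name: float(
                np.exp(np.log(self.median[name]) + self.sigma_log[name] * rng.standard_normal())
            )
            for name in ("R", "Rp", "I", "C")
        }
        return ERICParameters(**vals)


def _default_groups() -> dict[str, GroupDistribution]:
    def shifted(shift: dict[str, float]) -> GroupDistribution:
        return GroupDistribution(
            median={k: _CONTROL_MEDIAN[k] * shift[k] for k in _CONTROL_MEDIAN},
            sigma_log=dict(_CONTROL_SIGMA),
        )

    return {
        GROUP_CONTROL: shifted({k: 1.0 for k in _CONTROL_MEDIAN}),
        GROUP_NORMAL: shifted(_SHIFT_NORMAL),
        GROUP_ALTERED: shifted(_SHIFT_ALTERED),
    }


@dataclass
class CohortConfig:
    """Configuration of a synthetic oscillometry cohort.

    Defaults mirror the study population this package emulates: 25 healthy
    controls, 24 sarcoidosis patients with normal spirometry and 23 with
    altered spirometry, each examined three times with the replicates
    averaged.
    """

    n_control: int = 25
    n_normal: int = 24
    n_altered: int = 23
    replicates: int = 3
    noise: float = 0.03  # relative s.d. of multiplicative replicate noise
    seed: int = 7
    frequencies: np.ndarray = field(default_factory=lambda: DEFAULT_FREQUENCIES.copy())
    groups: dict[str, GroupDistribution] = field(default_factory=_default_groups)

    def __post_init__(self) -> None:
        for name, n in (
            ("n_control", self.n_control),
            ("n_normal", self.n_normal),
            ("n_altered", self.n_altered),
            ("replicates", self.replicates),
        ):
            if n <= 0:
                raise ValueError(f"{name} must be > 0, got {n}")
        if self.noise < 0:
            raise ValueError(f"noise must be >= 0, got {self.noise}")

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a config from YAML/JSON.  Only scalar fields are settable."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        allowed = {"n_control", "n_normal", "n_altered", "replicates", "noise", "seed"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "n_control": self.n_control,
            "n_normal": self.n_normal,
            "n_altered": self.n_altered,
            "replicates": self.replicates,
            "noise": self.noise,
            "seed": self.seed,
        }


@dataclass
class SubjectRecord:
    """One simulated subject: id, group, averaged spectrum and ground truth."""

    subject_id: str
    group: str
    spectrum: ImpedanceSpectrum
    true_params: ERICParameters | None = None
    replicate_spectra: list[ImpedanceSpectrum] | None = None

    @property
    def label(self) -> int:
        """Binary diagnosis label: 0 for control, 1 for disease."""
        return 0 if self.group == GROUP_CONTROL else 1


def simulate_cohort(config: CohortConfig | None = None) -> list[SubjectRecord]:
    """Simulate a full cohort of averaged oscillometry exams.

    Per subject: eRIC parameters are drawn from the group's log-normal
    distribution, each replicate spectrum is the forward model perturbed by
    independent multiplicative Gaussian noise on resistance and reactance at
    every frequency, and the stored spectrum is the arithmetic mean of the
    replicates.  The whole cohort is a pure function of ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(derive_seed(config.seed, "simulate"))
    sizes = {
        GROUP_CONTROL: config.n_control,
        GROUP_NORMAL: config.n_normal,
        GROUP_ALTERED: config.n_altered,
    }
    records: list[SubjectRecord] = []
    counter = 0
    for group, n in sizes.items():
        dist = config.groups[group]
        for _ in range(n):
            counter += 1
            # truncate to the measurable regime: every exam in the emulated
            # population has its resonance above the 4 Hz band edge, i.e.
            # negative reactance at 4 Hz (Cdyn and Ax well defined)
            for _attempt in range(100):
                params = dist.draw(rng)
                clean = eric_impedance(params, config.frequencies)
                if clean.reactance[0] < 0:
                    break
            else:
                raise RuntimeError(
                    f"could not draw parameters with X(4 Hz) < 0 for group {group}; "
                    "distribution incompatible with the measurable regime"
                )
            reps = []
            for _ in range(config.replicates):
                rfac = 1.0 + config.noise * rng.standard_normal(len(config.frequencies))
                xfac = 1.0 + config.noise * rng.standard_normal(len(config.frequencies))
                reps.append(
                    ImpedanceSpectrum(
                        frequencies=config.frequencies,
                        resistance=clean.resistance * rfac,
                        reactance=clean.reactance * xfac,
                    )
                )
            avg = ImpedanceSpectrum(
                frequencies=config.frequencies,
                resistance=np.mean([s.resistance for s in reps], axis=0),
                reactance=np.mean([s.reactance for s in reps], axis=0),
            )
            records.append(
                SubjectRecord(
                    subject_id=f"S{counter:03d}",
                    group=group,
                    spectrum=avg,
                    true_params=params,
                    replicate_spectra=reps,
                )
            )
    return records


def cohort_to_frames(records: list[SubjectRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format spectra table and labels table for a cohort.

    Returns ``(spectra, labels)`` where ``spectra`` has columns
    subject_id, replicate, frequency_hz, resistance, reactance (replicate 0
    is the stored average) and ``labels`` has subject_id, group.
    """
    rows = []
    for rec in records:
        reps = [rec.spectrum] if rec.replicate_spectra is None else rec.replicate_spectra
        for f, r, x in zip(rec.spectrum.frequencies, rec.spectrum.resistance, rec.spectrum.reactance):
            rows.append((rec.subject_id, 0, f, r, x))
        for i, spec in enumerate(reps, start=1):
            if rec.replicate_spectra is None:
                break
            for f, r, x in zip(spec.frequencies, spec.resistance, spec.reactance):
                rows.append((rec.subject_id, i, f, r, x))
    spectra = pd.DataFrame(
        rows, columns=["subject_id", "replicate", "frequency_hz", "resistance", "reactance"]
    )
    labels = pd.DataFrame(
        {"subject_id": [r.subject_id for r in records], "group": [r.group for r in records]}
    )
    return spectra, labels


def write_cohort(records: list[SubjectRecord], spectra_path, labels_path) -> None:
    spectra, labels = cohort_to_frames(records)
    spectra.to_csv(spectra_path, index=False)
    labels.to_csv(labels_path, index=False)


def read_cohort(spectra_path, labels_path) -> list[SubjectRecord]:
    """Reconstruct subject records (averaged spectra only) from the CSV pair."""
    spectra = pd.read_csv(spectra_path)
    labels = pd.read_csv(labels_path).set_index("subject_id")["group"]
    records = []
    for sid, sub in spectra[spectra["replicate"] == 0].groupby("subject_id", sort=False):
        sub = sub.sort_values("frequency_hz")
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                group=str(labels.loc[sid]),
                spectrum=ImpedanceSpectrum(
                    frequencies=sub["frequency_hz"].to_numpy(),
                    resistance=sub["resistance"].to_numpy(),
                    reactance=sub["reactance"].to_numpy(),
                ),
            )
        )
    return records
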