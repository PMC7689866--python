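"""Core domain types.

The package analyses two kinds of raw data:

* in vivo current-clamp recordings of MNTB principal neurons
  (:class:`TraceRecording`), from which excitatory postsynaptic potentials
  (EPSPs) are detected and attributed to discrete synaptic inputs, and
* 3D fluorescence stacks (:class:`VoxelVolume`) of the biocytin-filled soma
  and the VGluT-labelled presynaptic terminals, from which somatic contact
  areas are measured.

Synaptic strength is measured throughout as the EPSP maximal rate of rise
(RoR, in V/s), the standard strength proxy for this preparation because EPSP
amplitudes are truncated whenever the cell fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .errors import ParameterError

__all__ = [
    "Stimulus",
    "TraceRecording",
    "EPSPEvent",
    "IntensityGroup",
    "InputEstimate",
    "CellInputs",
    "SynapticInput",
    "CellGroundTruth",
    "CohortParams",
    "VolumeParams",
    "VoxelVolume",
    "SomaMask",
    "ClusterSet",
    "ContactReport",
    "StructureFunctionRecord",
    "PowerLawFit",
    "LogisticFit",
    "RegressionResult",
]


class Stimulus(NamedTuple):
    """One afferent-stimulation pulse."""

    time_s: float
    intensity_mA: float


@dataclass
class TraceRecording:
    """A single-channel membrane-potential recording.

    Parameters
    ----------
    samples:
        Membrane potential in mV.
    sampling_rate:
        Digitization rate in Hz (default 25 kHz).
    stimuli:
        Afferent stimulation pulses, strictly increasing in time.
    resting_potential:
        Nominal resting membrane potential in mV.
    metadata:
        Free-form provenance (seeds, generator ground truth, cell id...).
    """

    samples: np.ndarray
    sampling_rate: float = 25000.0
    stimuli: list[Stimulus] = field(default_factory=list)
    resting_potential: float = -70.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        self.stimuli = [Stimulus(*s) for s in self.stimuli]
        times = [s.time_s for s in self.stimuli]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("stimulus times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ParameterError("stimulus times must lie within the trace")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class EPSPEvent:
    """One detected postsynaptic event.

    ``rate_of_rise`` is the maximum of the smoothed dV/dt between onset and
    peak, truncated at the AP threshold when the EPSP triggers a spike.
    ``latency_ms`` is onset minus the nearest preceding stimulus time;
    ``evoked`` is true iff that latency falls in (1, 8] ms.
    """

    onset_s: float
    rate_of_rise: float  # V/s
    amplitude: float  # mV
    latency_ms: Optional[float] = None
    evoked: bool = False
    stimulus_intensity: Optional[float] = None
    stimulus_index: Optional[int] = None
    prespike_amplitude: Optional[float] = None  # peak-to-peak mV
    triggered_ap: bool = False


@dataclass
class IntensityGroup:
    """Evoked events pooled at one stimulation intensity."""

    intensity: float  # mA
    latencies: np.ndarray  # ms
    rors: np.ndarray  # V/s
    n_sweeps: int
    n_responding: int

    def __post_init__(self):
        self.latencies = np.asarray(self.latencies, dtype=float)
        self.rors = np.asarray(self.rors, dtype=float)
        if self.latencies.shape != self.rors.shape:
            raise ParameterError("latencies and rors must have equal length")
        if self.intensity <= 0:
            raise ParameterError("intensity must be positive")

    @property
    def response_rate(self) -> float:
        return self.n_responding / self.n_sweeps if self.n_sweeps else 0.0

    @property
    def mean_ror(self) -> float:
        return float(np.mean(self.rors)) if self.rors.size else 0.0

    @property
    def mean_latency(self) -> float:
        return float(np.mean(self.latencies)) if self.latencies.size else np.nan


@dataclass
class InputEstimate:
    """One identified synaptic input (per-input aggregate)."""

    mean_ror: float  # V/s
    ror_sd: float = 0.0
    mean_latency: Optional[float] = None  # ms
    source: str = "evoked"  # {"evoked", "spontaneous"}
    strong: bool = False
    prespike: bool = False
    prespike_amp: Optional[float] = None  # mV
    p_ap: Optional[float] = None
    n_events: int = 0
    recruitment_intensity: Optional[float] = None  # mA
    checked_against_spontaneous: bool = True

    def __post_init__(self):
        if self.mean_ror <= 0:
            raise ParameterError("mean_ror must be positive")
        if self.source not in ("evoked", "spontaneous"):
            raise ParameterError("source must be 'evoked' or 'spontaneous'")


@dataclass
class CellInputs:
    """Per-cell input roster, strongest first.

    ``competition_index`` is the ratio of the second strongest to the
    strongest input's mean RoR: 1 means two equally strong inputs, values
    near 0 a single dominant input.
    """

    age: float  # days
    inputs: list[InputEstimate]
    cell_id: str = ""

    def __post_init__(self):
        self.inputs = sorted(
            self.inputs,
            key=lambda i: (-i.mean_ror, i.mean_latency if i.mean_latency is not None else np.inf),
        )

    @property
    def competition_index(self) -> Optional[float]:
        if len(self.inputs) < 2:
            return None
        return self.inputs[1].mean_ror / self.inputs[0].mean_ror

    @property
    def strongest(self) -> InputEstimate:
        return self.inputs[0]


# --------------------------------------------------------------------------
# synthetic ground truth


@dataclass
class SynapticInput:
    """Ground-truth description of one synthetic input."""

    true_ror: float  # V/s, mean across trials
    recruitment_threshold: float  # mA
    activation_prob: float
    latency_mean: float  # ms
    latency_cv: float
    trial_cv: float  # per-trial RoR coefficient of variation
    is_calyceal: bool = False
    prespike_amp: Optional[float] = None  # peak-to-peak mV

    def __post_init__(self):
        if self.true_ror <= 0:
            raise ParameterError("true_ror must be positive")
        if not (0.0 < self.activation_prob <= 1.0):
            raise ParameterError("activation_prob must be in (0, 1]")
        if not (1.0 < self.latency_mean <= 8.0):
            raise ParameterError("latency_mean must be in (1, 8] ms")


@dataclass
class CellGroundTruth:
    """Full ground truth for one synthetic cell."""

    cell_id: str
    age: float  # days
    inputs: list[SynapticInput]
    true_contact_areas: np.ndarray  # µm², aligned with `inputs`
    soma_radius: float  # µm
    observed_rors: Optional[np.ndarray] = None  # noisy structure-function RoRs

    def __post_init__(self):
        self.true_contact_areas = np.asarray(self.true_contact_areas, dtype=float)
        if np.any(self.true_contact_areas < 0):
            raise ParameterError("contact areas must be non-negative")
        if sum(i.is_calyceal for i in self.inputs) > 1:
            raise ParameterError("at most one input may be calyceal")

    @property
    def strongest(self) -> Optional[SynapticInput]:
        return max(self.inputs, key=lambda i: i.true_ror) if self.inputs else None

    def sorted_rors(self) -> np.ndarray:
        return np.sort([i.true_ror for i in self.inputs])[::-1]


@dataclass
class CohortParams:
    """Parameters of the synthetic developmental cohort.

    Defaults encode the developmental statistics this generator emulates:
    the strongest input grows at 4.2 V/s per day from about 8 V/s at P2,
    the second strongest stays near 3.7 V/s, cells carry 5.6 +- 1.6 inputs,
    and input strength relates to terminal contact area through
    RoR = beta * area**alpha with beta = 6.8 V/s/µm^(2*alpha), alpha = 0.35.
    """

    n_cells: int = 32
    age_range: tuple[float, float] = (2.0, 8.0)
    strongest_growth: float = 4.2  # V/s per day
    strongest_intercept: float = 8.0  # V/s at age 2
    second_mean: float = 3.7  # V/s
    n_inputs_mean: float = 5.6
    n_inputs_sd: float = 1.6
    weak_ror_range: tuple[float, float] = (0.7, 2.0)
    beta: float = 6.8  # V/s per µm^(2*alpha)
    alpha: float = 0.35
    ror_noise_cv: tuple[float, float] = (0.07, 0.38)  # per-trial CV range
    strongest_spread: float = 0.25  # lognormal sigma, cell-to-cell
    second_spread: float = 0.30  # lognormal sigma, cell-to-cell
    sf_noise_sigma: float = 0.36  # lognormal sigma of observed vs true RoR
    threshold_range: tuple[float, float] = (0.08, 0.40)  # mA
    activation_prob_range: tuple[float, float] = (0.59, 1.0)
    latency_jitter_cv: tuple[float, float] = (0.010, 0.038)
    calyx_midpoint: float = 4.1  # days; prespike presence logistic
    calyx_steepness: float = 0.7  # days
    soma_radius_range: tuple[float, float] = (6.0, 8.0)  # µm
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("alpha and beta must be positive")
        lo, hi = self.age_range
        if not (2.0 <= lo <= hi <= 8.0):
            raise ParameterError("age_range must lie within [2, 8] days")
        if self.weak_ror_range[0] <= 0 or self.strongest_intercept <= 0 or self.second_mean <= 0:
            raise ParameterError("all rates of rise must be positive")


@dataclass
class VolumeParams:
    """Geometry and noise model of synthetic fluorescence volumes.

    Voxel sizes default to the SIM sampling this emulates: 41 nm lateral,
    110 nm axial, in (z, y, x) order.
    """

    voxel_size: tuple[float, float, float] = (0.110, 0.041, 0.041)  # µm, ZYX
    psf_sigma: tuple[float, float, float] = (0.12, 0.05, 0.05)  # µm, ZYX
    gaussian_sd: float = 0.0  # intensity units
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables
    shell_thickness: float = 0.25  # µm, radial extent of marker caps
    cleft_offset: float = 0.20  # µm, gap between soma surface and marker
    margin: float = 1.2  # µm of padding around the soma
    anisotropy: tuple[float, float, float] = (1.0, 0.96, 1.04)  # soma axes /radius
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be positive")
        if self.shell_thickness < min(self.voxel_size):
            raise ParameterError("shell_thickness must be >= 1 voxel")


# --------------------------------------------------------------------------
# volumes and segmentation products


@dataclass
class VoxelVolume:
    """A 3D intensity grid in ZYX order with physical voxel sizes (µm)."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (0.110, 0.041, 0.041)
    channel_name: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ParameterError("intensities must be a non-empty 3D array")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be positive")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class SomaMask:
    """Segmented cell body (boolean ZYX grid)."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    dilation_used: float = 0.0  # µm
    surface_area: Optional[float] = None  # µm², set by contact_report

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ClusterSet:
    """Labelled marker clusters: 26-connected, pairwise disjoint, labels 1..K."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    threshold_used: float = np.nan

    def __post_init__(self):
        self.labels = np.asarray(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def voxel_counts(self) -> np.ndarray:
        if self.n_clusters == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels.ravel(), minlength=self.n_clusters + 1)[1:]


@dataclass
class ContactReport:
    """Per-cluster somatic contact-area accounting.

    ``contact_ratio`` = largest cluster's contact area over the total
    contacted area; ``coverage_fraction`` = total contacted area over the
    soma surface area.
    """

    cluster_areas: np.ndarray  # µm², indexed by label-1
    soma_surface_area: float  # µm²
    dilation_used: float = 0.0  # µm

    def __post_init__(self):
        self.cluster_areas = np.asarray(self.cluster_areas, dtype=float)

    @property
    def total_contact_area(self) -> float:
        return float(self.cluster_areas.sum())

    @property
    def largest_area(self) -> float:
        return float(self.cluster_areas.max()) if self.cluster_areas.size else 0.0

    @property
    def second_largest_area(self) -> float:
        if self.cluster_areas.size < 2:
            return 0.0
        return float(np.sort(self.cluster_areas)[-2])

    @property
    def contact_ratio(self) -> Optional[float]:
        total = self.total_contact_area
        return self.largest_area / total if total > 0 else None

    @property
    def coverage_fraction(self) -> float:
        if self.soma_surface_area <= 0:
            return 0.0
        return min(1.0, self.total_contact_area / self.soma_surface_area)


# --------------------------------------------------------------------------
# statistics layer


@dataclass
class StructureFunctionRecord:
    """One cell's row in the structure-function table."""

    cell_id: str
    age: float
    strongest_ror: float
    second_ror: Optional[float] = None
    competition_index: Optional[float] = None
    largest_area: Optional[float] = None
    second_area: Optional[float] = None
    contact_ratio: Optional[float] = None
    prespike: bool = False
    prespike_amp: Optional[float] = None
    p_ap: Optional[float] = None


@dataclass
class PowerLawFit:
    """Log-log OLS fit of RoR = beta * area**alpha."""

    beta: float
    alpha: float
    se_beta: float
    se_alpha: float
    r_log: float
    F: float
    p: float
    n: int


@dataclass
class LogisticFit:
    """Fit of P(present) = 1 / (1 + exp(-(age - midpoint)/steepness))."""

    midpoint: float  # days
    steepness: float  # days
    se_midpoint: float
    se_steepness: float
    converged: bool


@dataclass
class RegressionResult:
    """OLS summary: coefficients (intercept first), SEs, t, F, df, p."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    F: float
    df: tuple[int, int]
    p: float
    p_coef: np.ndarray = field(default_factory=lambda: np.zeros(0))
    p_corrected: Optional[float] = None

    @property
    def slope(self) -> float:
        return float(self.params[1])
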