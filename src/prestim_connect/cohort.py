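"""Synthetic infant cohort generator.

Emulates the structure of an infant noxious-stimulation fMRI session: 13
term infants, TR 2.5 s, 142 volumes, 10 brief noxious stimuli at least 25 s
apart, and 15 ROIs grouped into three networks — the descending pain
modulatory system (DPMS), a topographically matched Control network, and the
Default Mode Network (DMN).

Each infant carries a latent DPMS coupling strength that scales shared
band-limited (0.01–0.08 Hz) fluctuations across DPMS ROIs and, with a
negative slope, sets the amplitude of the stimulus-evoked responses: infants
whose DPMS is more tightly coupled respond less. Control and DMN
fluctuation strengths are drawn independently of the latent coupling.
Ground-truth latents are stored on each record so downstream recovery is
directly testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .events import StimulusProtocol
from .hrf import BasisSet, HRFSpec, build_basis_set, build_design_matrix, calibrate_infant_hrf

__all__ = [
    "DEFAULT_NETWORKS",
    "CohortConfig",
    "strong_coupling_config",
    "targeted_edge_config",
    "null_coupling_config",
    "InfantRecord",
    "Cohort",
    "generate_protocol",
    "generate_infant",
    "generate_cohort",
    "render_volumes",
]

DEFAULT_NETWORKS: dict[str, tuple[str, ...]] = {
    "DPMS": ("ACC", "AI", "AMY", "mFG", "PAG", "RVM"),
    "Control": ("CAL", "CAU", "HIP", "PON", "RGY", "SMA"),
    "DMN": ("PCC", "IPL", "mSFG"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for synthetic cohorts.

    Amplitudes are in raw signal units on a baseline of ~1000, so percent
    change is amplitude/baseline*100. ``coupling_slope`` is the change in
    evoked amplitude (percent signal) per unit latent DPMS coupling;
    negative values reproduce the inverse psFC→response association.
    """

    n_infants: int = 13
    tr: float = 2.5
    n_volumes: int = 142
    n_stimuli: int = 10
    min_isi: float = 25.0
    isi_jitter: float = 6.0
    networks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_NETWORKS)
    )
    baseline: float = 1000.0
    noise_sd: float = 5.0
    drift_amplitude: float = 5.0
    shared_fluct_sd: float = 6.0
    dmn_fluct_factor: float = 1.5
    coupling_range: tuple[float, float] = (0.2, 1.0)
    coupling_slope: float = -2.0
    amplitude_intercept: float = 2.2
    amplitude_noise_sd: float = 0.12
    active_rois: tuple[str, ...] = ("ACC", "AI", "mFG", "SMA")
    ga_range: tuple[float, float] = (38.0, 43.0)
    ga_coupling_corr: float = 0.0
    dpms_mode: str = "network"  # "network" or "edge"
    dpms_edge: tuple[str, str] = ("ACC", "PAG")
    # scales the DPMS-wide shared factor; set to 0 in edge mode so that the
    # coupling is carried exclusively by the designated pair
    dpms_network_fluct_factor: float = 1.0
    silent_rois: tuple[str, ...] = ()  # ROIs carrying no network fluctuation
    n_motion_spikes: int = 0
    spike_magnitude: float = 50.0
    hrf: HRFSpec = field(default_factory=HRFSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli * self.min_isi >= self.n_volumes * self.tr:
            raise ValueError(
                "stimulation protocol cannot fit in the acquisition: "
                f"need > {self.n_stimuli * self.min_isi:.0f} s of scan"
            )
        if any(len(v) == 0 for v in self.networks.values()):
            raise ValueError("every network must contain at least one ROI")
        if self.dpms_mode not in ("network", "edge"):
            raise ValueError("dpms_mode must be 'network' or 'edge'")

    @property
    def roi_labels(self) -> tuple[str, ...]:
        out: list[str] = []
        for members in self.networks.values():
            out.extend(members)
        return tuple(out)

    @property
    def scan_duration(self) -> float:
        return self.n_volumes * self.tr


def strong_coupling_config(seed: int = 0, **overrides) -> CohortConfig:
    """Conditions for the parameter-recovery study.

    The inverse coupling is calibrated so that, pooling infants across many
    cohorts, the age-adjusted correlation between measured DPMS psFC and
    measured percent change is about -0.85 — the strong-association regime.
    Three-point pre-stimulus windows put an irreducible sampling-noise floor
    under the measured psFC, so the shared-fluctuation strength here is
    deliberately higher (and the white noise lower) than in the default
    study-structure configuration.
    """
    params = dict(
        coupling_range=(0.0, 1.3),
        noise_sd=2.5,
        shared_fluct_sd=9.0,
        amplitude_noise_sd=0.03,
        coupling_slope=-1.5,
        amplitude_intercept=2.1,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


def targeted_edge_config(seed: int = 0, **overrides) -> CohortConfig:
    """Conditions where a single ROI pair carries the psFC→amplitude coupling.

    The designated edge (default ACC–PAG) loads on its own latent-coupling
    factor; the DPMS-wide factor is damped so the pair dominates, and the
    activity mask sits on non-DPMS ROIs so that evoked-response tails cannot
    leak shared signal into DPMS pre-stimulus windows. A 40-infant cohort
    gives the edgewise screen enough precision that the loaded edge carries
    the largest |beta| in nearly every cohort.
    """
    params = dict(
        dpms_mode="edge",
        dpms_edge=("ACC", "PAG"),
        dpms_network_fluct_factor=0.4,
        n_infants=40,
        active_rois=("SMA", "CAL"),
        noise_sd=1.5,
        amplitude_noise_sd=0.01,
    )
    params.update(overrides)
    return strong_coupling_config(seed=seed, **params)


def null_coupling_config(seed: int = 0, **overrides) -> CohortConfig:
    """No psFC→amplitude coupling: evoked amplitude independent of the
    latent connectivity, for type-I-error calibration."""
    params = dict(coupling_slope=0.0, amplitude_intercept=1.2, seed=seed)
    params.update(overrides)
    return CohortConfig(**params)


@dataclass(frozen=True)
class InfantRecord:
    """One synthetic session plus every latent quantity used to build it."""

    id: str
    ga_weeks: float
    latent_coupling: float
    true_amplitude_pct: float
    protocol: StimulusProtocol
    roi_series: dict[str, np.ndarray]
    baselines: dict[str, float]
    ground_truth: dict

    @property
    def n_volumes(self) -> int:
        return len(next(iter(self.roi_series.values())))


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    infants: tuple[InfantRecord, ...]
    hrf: np.ndarray
    basis: BasisSet

    def __len__(self) -> int:
        return len(self.infants)

    def to_dir(self, path) -> None:
        """Write series/events/covariates/ground-truth files per infant."""
        import pandas as pd
        from pathlib import Path

        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        cov = []
        for rec in self.infants:
            sub = root / rec.id
            sub.mkdir(exist_ok=True)
            pd.DataFrame(rec.roi_series).to_csv(sub / "roi_series.csv", index=False)
            rec.protocol.to_tsv(sub / "events.tsv")
            with open(sub / "ground_truth.json", "w") as fh:
                json.dump(rec.ground_truth, fh, indent=2)
            cov.append({"id": rec.id, "ga_weeks": rec.ga_weeks})
        pd.DataFrame(cov).to_csv(root / "covariates.csv", index=False)
        manifest = {
            "n_infants": len(self.infants),
            "tr": self.config.tr,
            "n_volumes": self.config.n_volumes,
            "networks": {k: list(v) for k, v in self.config.networks.items()},
            "seed": self.config.seed,
        }
        with open(root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def generate_protocol(config: CohortConfig, rng: np.random.Generator) -> StimulusProtocol:
    """Jittered stimulus onsets with every gap >= the ISI floor.

    Gaps are min_isi plus a uniform jitter; onsets are continuous-valued so
    stimuli are not phase-locked to volume boundaries. Raises when the
    protocol cannot fit, reporting the scan length that would be required.
    """
    if config.n_stimuli == 0:
        return StimulusProtocol(np.empty(0), np.empty(0))
    lead_in = 4 * config.tr  # room for a full pre-stimulus window
    tail = config.min_isi  # let the last response evolve
    n_gaps = config.n_stimuli - 1
    required = lead_in + n_gaps * config.min_isi + tail
    slack = config.scan_duration - required
    if slack <= 0:
        raise ValueError(
            f"infeasible protocol: needs at least {required:.0f} s of scan, "
            f"have {config.scan_duration:.0f} s"
        )
    jitter_cap = min(config.isi_jitter, slack / max(n_gaps, 1) * 0.8)
    start = lead_in + rng.uniform(0.0, min(slack * 0.2, 2 * config.tr))
    gaps = config.min_isi + rng.uniform(0.0, jitter_cap, size=n_gaps)
    onsets = start + np.concatenate([[0.0], np.cumsum(gaps)])
    durations = np.full(config.n_stimuli, 1.0)
    protocol = StimulusProtocol(onsets, durations)
    protocol.validate(scan_duration=config.scan_duration, min_isi=config.min_isi)
    return protocol


def _bandlimited_factor(
    rng: np.random.Generator,
    n_volumes: int,
    tr: float,
    n_components: int = 6,
    band: tuple[float, float] = (0.01, 0.08),
) -> np.ndarray:
    """Unit-variance mixture of sinusoids confined to the slow BOLD band."""
    t = np.arange(n_volumes) * tr
    freqs = rng.uniform(band[0], band[1], n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_components)
    f = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    sd = f.std()
    if sd == 0:  # pragma: no cover - measure-zero draw
        return np.zeros(n_volumes)
    return (f - f.mean()) / sd


def _correlated_uniforms(
    rng: np.random.Generator, corr: float
) -> tuple[float, float]:
    """Two U(0,1) draws with Gaussian-copula correlation ``corr``."""
    z = rng.standard_normal(2)
    z2 = corr * z[0] + np.sqrt(max(0.0, 1.0 - corr**2)) * z[1]
    return float(norm.cdf(z[0])), float(norm.cdf(z2))


def generate_infant(
    config: CohortConfig,
    infant_index: int,
    rng: np.random.Generator,
    basis: BasisSet | None = None,
) -> InfantRecord:
    """One synthetic session.

    Per ROI: baseline + shared within-network slow fluctuation (network
    factor x loading x strength) + linear drift + white noise, plus the
    evoked-response train on the activity-mask ROIs. The evoked regressor is
    built through the same design-matrix path used for fitting, so noise-free
    sessions are exactly recoverable by the GLM.
    """
    if basis is None:
        basis = _calibrated_basis(config.hrf)[1]
    u_coupling, u_ga = _correlated_uniforms(rng, config.ga_coupling_corr)
    lo, hi = config.coupling_range
    coupling = lo + (hi - lo) * u_coupling
    ga = config.ga_range[0] + (config.ga_range[1] - config.ga_range[0]) * u_ga
    amplitude_pct = (
        config.amplitude_intercept
        + config.coupling_slope * coupling
        + rng.normal(0.0, config.amplitude_noise_sd)
    )

    protocol = generate_protocol(config, rng)
    if protocol.n_stimuli:
        design = build_design_matrix(
            protocol, basis, config.n_volumes, config.tr
        )
        evoked_regressor = design.task[:, 0]
    else:
        evoked_regressor = np.zeros(config.n_volumes)

    t = np.arange(config.n_volumes) * config.tr

    # independent slow factors per network; strengths for Control/DMN are
    # drawn independently of the DPMS latent coupling
    factors: dict[str, np.ndarray] = {}
    strengths: dict[str, float] = {}
    for name in config.networks:
        factors[name] = _bandlimited_factor(rng, config.n_volumes, config.tr)
        u = rng.uniform(lo, hi)
        if name == "DPMS":
            strengths[name] = (
                config.shared_fluct_sd
                * config.dpms_network_fluct_factor
                * (coupling if config.dpms_mode == "network" else u)
            )
        elif name == "DMN":
            strengths[name] = config.shared_fluct_sd * config.dmn_fluct_factor * u
        else:
            strengths[name] = config.shared_fluct_sd * u
    edge_factor = (
        _bandlimited_factor(rng, config.n_volumes, config.tr)
        if config.dpms_mode == "edge"
        else None
    )

    spike_volumes: tuple[int, ...] = ()
    if config.n_motion_spikes:
        candidates = np.arange(1, config.n_volumes)
        spike_volumes = tuple(
            sorted(
                int(v)
                for v in rng.choice(
                    candidates, size=config.n_motion_spikes, replace=False
                )
            )
        )

    roi_series: dict[str, np.ndarray] = {}
    baselines: dict[str, float] = {}
    loadings: dict[str, float] = {}
    drift_slopes: dict[str, float] = {}
    for network, members in config.networks.items():
        for roi in members:
            base = config.baseline * rng.uniform(0.9, 1.1)
            loading = rng.uniform(0.8, 1.2)
            if roi in config.silent_rois:
                loading = 0.0
            drift_slope = rng.uniform(-1.0, 1.0) * config.drift_amplitude
            signal = (
                base
                + drift_slope * (t / config.scan_duration)
                + strengths[network] * loading * factors[network]
            )
            if edge_factor is not None and roi in config.dpms_edge:
                signal = signal + config.shared_fluct_sd * coupling * edge_factor
            if roi in config.active_rois:
                # amplitude is a percent of the ROI's own baseline, so the
                # Featquery-style percent change recovers it directly
                signal = signal + (amplitude_pct / 100.0 * base) * evoked_regressor
            if config.noise_sd > 0:
                signal = signal + rng.normal(0.0, config.noise_sd, config.n_volumes)
            for v in spike_volumes:
                signal[v] += config.spike_magnitude
            roi_series[roi] = signal
            baselines[roi] = base
            loadings[roi] = loading
            drift_slopes[roi] = drift_slope

    ground_truth = {
        "latent_coupling": coupling,
        "true_amplitude_pct": amplitude_pct,
        "ga_weeks": ga,
        "network_fluct_strengths": strengths,
        "roi_loadings": loadings,
        "drift_slopes": drift_slopes,
        "active_rois": list(config.active_rois),
        "spike_volumes": list(spike_volumes),
        "onsets": protocol.onsets.tolist(),
    }
    return InfantRecord(
        id=f"infant{infant_index:02d}",
        ga_weeks=ga,
        latent_coupling=coupling,
        true_amplitude_pct=amplitude_pct,
        protocol=protocol,
        roi_series=roi_series,
        baselines=baselines,
        ground_truth=ground_truth,
    )


@lru_cache(maxsize=4)
def _calibrated_basis(spec: HRFSpec) -> tuple[np.ndarray, BasisSet]:
    hrf = calibrate_infant_hrf(spec)
    return hrf, build_basis_set(hrf, spec.dt)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Deterministic cohort: a fixed seed reproduces every sample exactly."""
    hrf, basis = _calibrated_basis(config.hrf)
    children = np.random.SeedSequence(config.seed).spawn(config.n_infants)
    infants = tuple(
        generate_infant(config, i, np.random.default_rng(children[i]), basis)
        for i in range(config.n_infants)
    )
    return Cohort(config=config, infants=infants, hrf=hrf, basis=basis)


# --- volume rendering -------------------------------------------------------

_BLOCK = 2  # ROI blocks are _BLOCK^3 voxels


def render_volumes(
    record: InfantRecord,
    grid_shape: tuple[int, int, int] = (20, 20, 12),
    voxel_noise_sd: float = 0.0,
    dropout_roi: str | None = None,
    dropout_fraction: float = 0.0,
    dropout_loss: float = 0.15,
    weighted_roi: str = "RVM",
    rng: np.random.Generator | None = None,
):
    """Render a session as a small 4D NIfTI with one voxel block per ROI.

    Each ROI occupies a disjoint cube carrying its series plus optional
    voxelwise noise. ``dropout_fraction`` of the voxels in ``dropout_roi``
    are attenuated by ``dropout_loss`` (>10% triggers the exclusion rule
    downstream); ``weighted_roi`` gets a non-binary mask (weights 1.0/0.5).

    Returns (image4d, masks, info) with nibabel images and per-ROI
    :class:`~prestim_connect.extraction.ROIMask`-compatible mask images.
    """
    import nibabel as nib

    if rng is None:
        rng = np.random.default_rng(0)
    labels = list(record.roi_series)
    nx, ny, nz = grid_shape
    pitch = _BLOCK + 2
    per_row = max((nx - 1) // pitch, 1)
    n_vol = record.n_volumes
    data = np.zeros((*grid_shape, n_vol), dtype=np.float32)
    occupancy = np.zeros(grid_shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    info: dict[str, dict] = {}

    for k, label in enumerate(labels):
        i, j = divmod(k, per_row)
        x0, y0, z0 = 1 + j * pitch, 1 + i * pitch, nz // 2 - 1
        if x0 + _BLOCK > nx or y0 + _BLOCK > ny or z0 + _BLOCK > nz:
            raise ValueError(
                f"grid {grid_shape} too small to place {len(labels)} disjoint ROIs"
            )
        sl = np.s_[x0 : x0 + _BLOCK, y0 : y0 + _BLOCK, z0 : z0 + _BLOCK]
        if occupancy[sl].any():
            raise ValueError(f"ROI {label!r} placement overlaps an earlier ROI")
        occupancy[sl] = True

        series = record.roi_series[label]
        block = np.broadcast_to(series, (_BLOCK, _BLOCK, _BLOCK, n_vol)).copy()
        if voxel_noise_sd > 0:
            block += rng.normal(0.0, voxel_noise_sd, block.shape)

        attenuated: list[tuple[int, ...]] = []
        if label == dropout_roi and dropout_fraction > 0:
            flat = [
                (a, b, c)
                for a in range(_BLOCK)
                for b in range(_BLOCK)
                for c in range(_BLOCK)
            ]
            n_att = int(round(dropout_fraction * len(flat)))
            for vox in flat[:n_att]:
                block[vox] *= 1.0 - dropout_loss
                attenuated.append(vox)

        data[sl] += block
        mask = np.zeros(grid_shape, dtype=np.float32)
        mask[sl] = 1.0
        if label == weighted_roi:
            half = mask[sl].copy()
            half.flat[: half.size // 2] = 0.5
            mask[sl] = half
        masks[label] = mask
        info[label] = {
            "origin": (x0, y0, z0),
            "attenuated_voxels": [
                (x0 + a, y0 + b, z0 + c) for (a, b, c) in attenuated
            ],
        }

    affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    mask_imgs = {k: nib.Nifti1Image(v, affine) for k, v in masks.items()}
    return img, mask_imgs, info


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["hrf"] = asdict(config.hrf)
    return d
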