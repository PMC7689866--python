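"""End-to-end orchestration: simulate -> detect -> identify -> segment ->
correlate, with config, provenance and fixture generation.

Every stage writes its outputs under ``out_dir`` with the config hash and
seeds recorded, so a rerun with the same config is byte-identical and any
output difference is explained by a config difference.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, seg3d
from .datatypes import CellGroundTruth, CohortParams, StructureFunctionRecord, SynapticInput, VolumeParams
from .errors import CalyxSFError, StageError
from .inputs import identify_inputs
from .sfstats import powerlaw_fit, regression_f
from .synth import make_cohort, synth_spont_activity, synth_stim_experiment, synth_volume

__all__ = ["PipelineConfig", "run", "make_fixtures", "DEFAULT_INTENSITIES"]

log = logging.getLogger("calyxsf")

DEFAULT_INTENSITIES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45)


@dataclass
class PipelineConfig:
    """Pipeline configuration. Analysis defaults are the field's standard
    values: 0.7 V/s minimal RoR, (1, 8] ms evoked window, summed Welch t
    threshold 6 with a 20% RoR increase, +-0.5 ms subtraction tolerance,
    10 V/s strong threshold, 400 nm probe at 40% fill, 26-connectivity, and
    a 0.16-0.76 µm dilation search."""

    seed: int = 0
    n_cells: int = 20
    out_dir: str = "calyxsf_out"
    # stage toggles
    simulate: bool = True
    detect: bool = True
    identify: bool = True
    segment: bool = True
    correlate: bool = True
    # physiology protocol
    intensities: tuple = DEFAULT_INTENSITIES
    sweeps_per_level: int = 30
    spont_duration_s: float = 20.0
    # detection / identification parameters
    min_ror: float = 0.7
    evoked_window_ms: tuple = (1.0, 8.0)
    t_sum_threshold: float = 6.0
    min_increase: float = 0.20
    latency_tol_ms: float = 0.5
    strong_threshold: float = 10.0
    # segmentation parameters
    probe_radius_um: float = 0.4
    fill_frac: float = 0.40
    min_cluster_voxels: int = 10
    dilation_search_um: tuple = (0.16, 0.76)
    dilation_step_um: float = 0.041
    # volume scale: multiply SIM voxel sizes (>1 = coarser, faster)
    voxel_scale: float = 1.0
    soma_radius_range: tuple = (3.0, 4.0)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise CalyxSFError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**doc)
        for f in ("intensities", "evoked_window_ms", "dilation_search_um", "soma_radius_range"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(io.jsonable(asdict(self)), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(io.jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _volume_params(cfg: PipelineConfig, seed: int) -> VolumeParams:
    s = cfg.voxel_scale
    vs = (0.110 * s, 0.041 * s, 0.041 * s)
    return VolumeParams(
        voxel_size=vs,
        psf_sigma=(0.12, 0.05, 0.05),
        gaussian_sd=8.0,
        cleft_offset=0.30,
        margin=max(1.2, 10.5 * max(vs)),
        seed=seed,
    )


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the cohort
    report (also written to ``out_dir``). Deterministic for a fixed config."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = dict(config_hash=config.hash(), seed=config.seed, version=__version__)
    config.to_yaml(out / "config.yaml")
    log.info("config hash %s", provenance["config_hash"])
    for name, value in (
        ("min_ror", config.min_ror),
        ("evoked_window_ms", config.evoked_window_ms),
        ("t_sum_threshold", config.t_sum_threshold),
        ("min_increase", config.min_increase),
        ("strong_threshold", config.strong_threshold),
        ("dilation_search_um", config.dilation_search_um),
    ):
        log.info("threshold %s = %s", name, value)

    report: dict = {"provenance": provenance}
    try:
        cohort = make_cohort(
            CohortParams(
                n_cells=config.n_cells,
                seed=config.seed,
                soma_radius_range=tuple(config.soma_radius_range),
            )
        )
    except CalyxSFError as exc:
        raise StageError("simulate", str(exc)) from exc

    records: list[StructureFunctionRecord] = []
    for k, cell in enumerate(cohort):
        rec = StructureFunctionRecord(cell_id=cell.cell_id, age=cell.age, strongest_ror=np.nan)
        if config.detect and config.identify:
            try:
                stim = synth_stim_experiment(
                    cell, list(config.intensities), config.sweeps_per_level, seed=config.seed * 100003 + k
                )
                spont = synth_spont_activity(
                    cell, config.spont_duration_s, seed=config.seed * 100003 + k + 1
                )
                ci = identify_inputs(
                    stim, spont, cell.age, cell.cell_id,
                    min_ror=config.min_ror, strong_threshold=config.strong_threshold,
                )
            except CalyxSFError as exc:
                raise StageError("identify", f"{cell.cell_id}: {exc}") from exc
            rec.strongest_ror = ci.inputs[0].mean_ror
            rec.second_ror = ci.inputs[1].mean_ror if len(ci.inputs) > 1 else None
            rec.competition_index = ci.competition_index
            rec.prespike = ci.inputs[0].prespike
            rec.prespike_amp = ci.inputs[0].prespike_amp
            rec.p_ap = ci.inputs[0].p_ap
            io.write_cell_json(ci, out / f"{cell.cell_id}_inputs.json")
        if config.segment:
            try:
                vparams = _volume_params(config, config.seed * 7 + k)
                fill, marker, _ = synth_volume(cell, vparams)
                # the probe must span at least one voxel on every axis
                probe_r = max(config.probe_radius_um, max(vparams.voxel_size))
                soma = seg3d.sphere_floodfill(fill, radius=probe_r, fill_frac=config.fill_frac)
                clusters = seg3d.floodfill_clusters(marker, min_size=config.min_cluster_voxels)
                d = seg3d.optimize_dilation(
                    soma, clusters, search=tuple(config.dilation_search_um), step=config.dilation_step_um
                )
                contact = seg3d.contact_report(seg3d.dilate_soma(soma, d), clusters)
            except CalyxSFError as exc:
                raise StageError("segment", f"{cell.cell_id}: {exc}") from exc
            rec.largest_area = contact.largest_area
            rec.second_area = contact.second_largest_area
            rec.contact_ratio = contact.contact_ratio
            io.write_contact_report(contact, out / f"{cell.cell_id}_contact.json")
        records.append(rec)

    io.write_cohort_tsv(records, out / "cohort.tsv")
    report["n_cells"] = len(records)

    if config.correlate:
        try:
            ok = [
                r for r in records
                if r.largest_area and r.largest_area > 0 and np.isfinite(r.strongest_ror)
            ]
            if len(ok) >= 3:
                fit = powerlaw_fit([r.largest_area for r in ok], [r.strongest_ror for r in ok])
                report["powerlaw"] = io.jsonable(asdict(fit))
            phys = [r for r in records if np.isfinite(r.strongest_ror)]
            if len(phys) >= 3:
                ages = np.array([r.age for r in phys])
                res = regression_f(ages, np.array([r.strongest_ror for r in phys]))
                report["strongest_age_slope"] = float(res.slope)
                ci_rows = [r for r in phys if r.competition_index is not None]
                if len(ci_rows) >= 3:
                    res_ci = regression_f(
                        np.array([r.age for r in ci_rows]),
                        np.array([r.competition_index for r in ci_rows]),
                    )
                    report["competition_index_slope"] = float(res_ci.slope)
        except CalyxSFError as exc:
            raise StageError("correlate", str(exc)) from exc

    (out / "report.json").write_text(json.dumps(io.jsonable(report), indent=1, sort_keys=True))
    return report


def developmental_recovery(
    n_cohorts: int = 50,
    n_cells: int = 32,
    base_seed: int = 0,
    intensities=DEFAULT_INTENSITIES,
    sweeps_per_level: int = 30,
    spont_duration_s: float = 20.0,
) -> dict:
    """Recover the developmental statistics from synthetic cohorts run
    through the full physiology pipeline (detection + identification).

    Per cohort: regress the identified strongest input's RoR on age, take
    the grand mean of the second strongest input's RoR, and fit the
    competition-index age slope. Returns the per-cohort values plus their
    medians -- the estimator of choice for a stochastic pipeline.
    """
    slopes, second_means, ci_slopes = [], [], []
    for c in range(n_cohorts):
        cohort = make_cohort(CohortParams(n_cells=n_cells, seed=base_seed * 1000003 + c))
        ages, strongest, seconds, cis = [], [], [], []
        for k, cell in enumerate(cohort):
            s = base_seed * 1000003 + c * 7919 + k
            stim = synth_stim_experiment(cell, list(intensities), sweeps_per_level, seed=s)
            spont = synth_spont_activity(cell, spont_duration_s, seed=s + 500009)
            ci = identify_inputs(stim, spont, cell.age, cell.cell_id)
            ages.append(cell.age)
            strongest.append(ci.inputs[0].mean_ror)
            if len(ci.inputs) > 1:
                seconds.append(ci.inputs[1].mean_ror)
                cis.append((cell.age, ci.competition_index))
        slopes.append(regression_f(np.array(ages), np.array(strongest)).slope)
        second_means.append(float(np.mean(seconds)))
        if len(cis) >= 3:
            arr = np.array(cis)
            ci_slopes.append(regression_f(arr[:, 0], arr[:, 1]).slope)
    return dict(
        slopes=slopes,
        second_means=second_means,
        ci_slopes=ci_slopes,
        median_slope=float(np.median(slopes)),
        median_second_mean=float(np.median(second_means)),
        median_ci_slope=float(np.median(ci_slopes)) if ci_slopes else np.nan,
        n_cohorts=n_cohorts,
        n_cells=n_cells,
    )


# --------------------------------------------------------------------------
# fixtures


def _fixture_cell(cell_id, age, rors, calyceal, rng) -> CellGroundTruth:
    inputs = []
    for j, r in enumerate(rors):
        inputs.append(
            SynapticInput(
                true_ror=r,
                recruitment_threshold=float(0.10 + 0.07 * j),
                activation_prob=0.9,
                latency_mean=float(1.8 + 0.9 * j),
                latency_cv=0.023,
                trial_cv=0.15,
                is_calyceal=calyceal and j == 0,
                prespike_amp=0.30 if (calyceal and j == 0) else None,
            )
        )
    areas = (np.asarray(rors) / 6.8) ** (1 / 0.35)
    return CellGroundTruth(
        cell_id=cell_id, age=age, inputs=inputs, true_contact_areas=areas,
        soma_radius=3.0, observed_rors=np.asarray(rors, float),
    )


def make_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write a small fixed cohort used by the test suite and demos: one
    calyceal P6-like cell, one intermediate P4-like cell and two immature
    P2-like cells, each with stimulation + spontaneous traces, two-channel
    volumes (at 4x coarser voxels than SIM, for speed) and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cells = [
        _fixture_cell("p6_calyceal", 6.5, [26.0, 3.5, 1.5, 0.9], True, rng),
        _fixture_cell("p4_intermediate", 4.0, [14.0, 4.0, 1.8, 1.2, 0.8], False, rng),
        _fixture_cell("p2_immature_a", 2.5, [6.0, 3.5, 1.6, 1.0, 0.8], False, rng),
        _fixture_cell("p2_immature_b", 2.2, [5.0, 4.0, 1.4, 0.9], False, rng),
    ]
    paths = []
    for k, cell in enumerate(cells):
        cdir = out / cell.cell_id
        cdir.mkdir(exist_ok=True)
        stim = synth_stim_experiment(cell, [0.1, 0.2, 0.3, 0.4], sweeps_per_level=10, seed=seed + k)
        spont = synth_spont_activity(cell, 10.0, seed=seed + 100 + k)
        io.write_trace(stim, cdir / "stim.csv")
        io.write_trace(spont, cdir / "spont.csv")
        vp = VolumeParams(
            voxel_size=(0.44, 0.164, 0.164), psf_sigma=(0.2, 0.1, 0.1),
            gaussian_sd=6.0, cleft_offset=0.30, margin=4.7, seed=seed + 200 + k,
        )
        fill, marker, true_report = synth_volume(cell, vp)
        io.write_volume(fill, cdir / "fill.tif")
        io.write_volume(marker, cdir / "marker.tif")
        truth = dict(
            cell_id=cell.cell_id,
            age_days=cell.age,
            true_rors=[i.true_ror for i in cell.inputs],
            calyceal=[i.is_calyceal for i in cell.inputs],
            prespike_amp=[i.prespike_amp for i in cell.inputs],
            true_contact_areas_um2=cell.true_contact_areas,
            true_report_areas_um2=true_report.cluster_areas,
            seed=seed,
        )
        (cdir / "truth.json").write_text(json.dumps(io.jsonable(truth), indent=1))
        paths.append(cdir)
    return paths
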