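"""End-to-end orchestration of the synthetic drug-relaxation experiment.

For each protein the pipeline ties the two measurement arms to one shared
ground truth: the FRAP arm simulates noisy recovery traces from the
protein's (k_on, k_off), averages and fits them, and converts the fit to
K_dis = k_off − k_on per minute; the imaging arm renders a movie whose
adhesions decay with τ = 1/K_dis, segments and tracks them, and fits the
measured disassembly curve.  The comparison of predicted exp(−K_dis·t)
against the measured curve is the synthetic analogue of comparing
FRAP-calculated and movie-measured disassembly.

A single run seed fans out to per-protein, per-arm child seeds through
``numpy.random.SeedSequence`` so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from fa_relax import io as fio
from fa_relax.adhesion_imaging import SegmentationConfig, estimate_bleach_correction, segment_movie
from fa_relax.adhesion_tracking import classify_all, lifespan_table, link_tracks
from fa_relax.frap_model import ExchangeParameters, fit_exchange, normalize_and_average
from fa_relax.kinetics_analysis import (
    compare_disassembly,
    compute_kdis,
    fit_single_exponential,
    intensity_decay_curve,
    plot_disassembly,
    predicted_disassembly,
    ranking_concordance,
    survival_curve,
)
from fa_relax.synthetic_data import MovieConfig, generate_frap_dataset, generate_movie

logger = logging.getLogger("fa_relax")

__all__ = ["ProteinSpec", "PipelineConfig", "run_pipeline", "demo_config"]

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class ProteinSpec:
    """Ground-truth exchange kinetics of one tagged protein (rates in 1/s)."""

    name: str
    group: str  # fast | mid | slow
    k_on_s: float
    k_off_s: float

    @property
    def k_dis_per_min(self) -> float:
        return (self.k_off_s - self.k_on_s) * SECONDS_PER_MINUTE

    @property
    def tau_min(self) -> float:
        kd = self.k_dis_per_min
        return 1.0 / kd if kd > 0 else float("inf")


def _default_proteins() -> list[ProteinSpec]:
    # one representative per decay group; k_off − k_on matches the group τ
    return [
        ProteinSpec("zyxin-like", "fast", k_on_s=2.0e-3, k_off_s=2.0e-3 + 1 / (7.5 * 60)),
        ProteinSpec("paxillin-like", "mid", k_on_s=2.0e-3, k_off_s=2.0e-3 + 1 / (16.0 * 60)),
        ProteinSpec("vinculin-like", "slow", k_on_s=1.5e-3, k_off_s=1.5e-3 + 1 / (26.5 * 60)),
    ]


@dataclass
class PipelineConfig:
    """Everything a run needs; optional paths switch a stage to real data."""

    seed: int = 0
    out_dir: str | None = None
    proteins: list[ProteinSpec] = field(default_factory=_default_proteins)
    # FRAP arm
    n_traces: int = 25
    frap_noise_sd: float = 0.02
    d_c: float = 1.2
    n_c: float = 1000.0
    w: float = 0.385
    r_fa: float = 0.56
    k_bleach: float = 2.2
    # imaging arm
    movie: MovieConfig = field(default_factory=MovieConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    max_displacement_um: float = 1.0
    max_gap_frames: int = 1
    peripheral_band: float = 0.25
    measured_kind: str = "intensity"  # intensity | survival
    comparison_window_min: tuple[float, float] = (0.0, 60.0)
    # optional real inputs
    movie_paths: dict | None = None  # protein name -> TIFF path
    trace_paths: dict | None = None  # protein name -> CSV path

    def validate(self) -> None:
        if self.measured_kind not in ("intensity", "survival"):
            raise ValueError("measured_kind must be 'intensity' or 'survival'")
        names = [p.name for p in self.proteins]
        if len(set(names)) != len(names):
            raise ValueError("protein names must be unique")
        for p in self.proteins:
            if p.group not in ("fast", "mid", "slow"):
                raise ValueError(f"protein {p.name}: unknown group {p.group!r}")
        for paths in (self.movie_paths, self.trace_paths):
            if paths:
                for name, path in paths.items():
                    if not Path(path).exists():
                        raise FileNotFoundError(f"input for {name} not found: {path}")


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small configuration that runs the whole chain in a few minutes."""
    return PipelineConfig(seed=seed)


def _analyze_movie(frames, cell_mask, cfg: PipelineConfig, movie_cfg: MovieConfig):
    """Shared imaging chain: segment → track → classify → bleach-correct → curves."""
    labels, records = segment_movie(frames, movie_cfg.pixel_size, cfg.segmentation,
                                    cell_mask=cell_mask)
    tracks = link_tracks(records, movie_cfg.pixel_size, cfg.max_displacement_um,
                         cfg.max_gap_frames)
    if cell_mask is not None:
        classify_all(tracks, cell_mask, cfg.peripheral_band)
    factors = estimate_bleach_correction(frames, cell_mask, labels > 0)
    cohort = [t for t in tracks
              if t.alive_at(movie_cfg.drug_frame)
              and (t.location_class in (None, "peripheral"))]
    surv = survival_curve(cohort, movie_cfg.drug_frame, movie_cfg.frame_interval,
                          movie_cfg.n_frames)
    inten = intensity_decay_curve(cohort, movie_cfg.drug_frame, movie_cfg.frame_interval,
                                  movie_cfg.n_frames, factors)
    return labels, records, tracks, factors, surv, inten


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full experiment; returns (and optionally writes) the report."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed, "proteins": {}}
    predicted_rates: dict[str, float] = {}
    measured_rates: dict[str, float] = {}
    for protein, child in zip(config.proteins, root.spawn(len(config.proteins))):
        frap_seed, movie_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2))
        logger.info("processing %s (group=%s)", protein.name, protein.group)

        # --- FRAP arm ---
        if config.trace_paths and protein.name in config.trace_paths:
            curves = fio.read_traces_csv(config.trace_paths[protein.name])
        else:
            params = ExchangeParameters(
                d_c=config.d_c, k_on=protein.k_on_s, k_off=protein.k_off_s,
                n_fa=config.n_c * protein.k_on_s / protein.k_off_s, n_c=config.n_c,
                w=config.w, k_bleach=config.k_bleach, r_fa=config.r_fa,
            )
            curves = generate_frap_dataset(params, config.frap_noise_sd,
                                           config.n_traces, frap_seed).curves
        avg = normalize_and_average(curves)
        n_fa_fixed = config.n_c * protein.k_on_s / protein.k_off_s
        xfit = fit_exchange(avg, d_c=config.d_c, n_fa=n_fa_fixed, n_c=config.n_c,
                            w=config.w, r_fa=config.r_fa)
        kdis = compute_kdis(xfit.k_on * SECONDS_PER_MINUTE, xfit.k_off * SECONDS_PER_MINUTE,
                            protein=protein.name)

        # --- imaging arm (movie τ derives from the same ground truth) ---
        movie_cfg = replace(
            config.movie,
            protein_group=protein.group,
            tau_presets_min={**config.movie.tau_presets_min, protein.group: protein.tau_min},
            seed=movie_seed,
        )
        if config.movie_paths and protein.name in config.movie_paths:
            frames = fio.read_movie_tiff(config.movie_paths[protein.name])
            cell_mask = None
            movie = None
        else:
            movie = generate_movie(movie_cfg)
            frames, cell_mask = movie.frames, movie.cell_mask
        labels, records, tracks, factors, surv, inten = _analyze_movie(
            frames, cell_mask, config, movie_cfg)
        measured = inten if config.measured_kind == "intensity" else surv
        mfit = fit_single_exponential(measured)

        # --- prediction and comparison ---
        pred = predicted_disassembly(kdis.k_dis, measured.times)
        comparison = compare_disassembly(pred, measured, config.comparison_window_min)
        predicted_rates[protein.name] = kdis.k_dis
        if mfit.success:
            measured_rates[protein.name] = 1.0 / mfit.tau

        entry = {
            "group": protein.group,
            "k_on_true_s": protein.k_on_s,
            "k_off_true_s": protein.k_off_s,
            "k_on_fit_s": xfit.k_on,
            "k_off_fit_s": xfit.k_off,
            "r_f": xfit.r_f,
            "t_half_s": xfit.t_half,
            "k_dis_per_min": kdis.k_dis,
            "kinetic_state": kdis.state,
            "tau_true_min": protein.tau_min,
            "tau_measured_min": mfit.tau if mfit.success else None,
            "n_tracks": len(tracks),
            "rms": comparison.rms,
            "rate_ratio": comparison.rate_ratio,
        }
        report["proteins"][protein.name] = entry
        if out_dir:
            pdir = out_dir / protein.name
            pdir.mkdir(exist_ok=True)
            lifespan_table(tracks, movie_cfg.frame_interval,
                           movie_cfg.drug_frame).to_csv(pdir / "lifespans.csv", index=False)
            curves_df = pd.concat([
                pd.DataFrame({"kind": c.kind, "time_min": c.times, "value": c.value})
                for c in (surv, inten, pred)
            ])
            curves_df.to_csv(pdir / "curves.csv", index=False)
            fio.write_report_json(pdir / "fits.json", entry, config)
            plot_disassembly([surv, inten, pred], pdir / "comparison.png",
                             title=protein.name)
            if movie is not None:
                fio.write_movie_tiff(pdir / "movie.tif", frames)
                movie.summary.to_csv(pdir / "ground_truth.csv", index=False)

    if len(measured_rates) >= 2:
        report["ranking_concordance"] = ranking_concordance(
            {k: v for k, v in predicted_rates.items() if k in measured_rates},
            measured_rates,
        )
    if out_dir:
        fio.write_report_json(out_dir / "report.json", report, config)
    return report
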