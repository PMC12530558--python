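"""End-to-end analysis pipeline: generate → standardise → repair →
morphometry → spines → simulate.

The pipeline runs on a synthetic cohort with known ground truth (or on SWC
files supplied by the user), writes per-stage artifacts under ``out_dir`` and
a single ``summary.json`` with the headline statistics.  Every random stage
takes an explicit seed, so a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import cable, repair, spines, synth
from .morphometry import neuron_morphometry, partition_segments
from .swc import read_swc, resample, standardize, write_swc

log = logging.getLogger("spnmorph")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed input data (exit code 3)."""


class NumericalError(RuntimeError):
    """A fit or solver failed (exit code 4)."""


@dataclass
class PipelineConfig:
    species: str = "mouse"
    out_dir: str = "spnmorph_out"
    n_cells: int = 6
    seed: int = 0
    swc_dir: str | None = None        # use existing SWCs instead of generating
    # standardisation / resampling
    shrink_z: float = 1.0             # 1.7 for slice reconstructions
    resample_step: float = 3.0
    resample_upscale: float = 1.01
    # repair
    z_threshold: float | None = None  # species default when None
    n_candidates: int = 25
    slab_soma_depth: float = 40.0
    # spines
    spine_bin_width: float = 10.0
    # simulation
    sim_dt: float = 0.05
    run_simulation: bool = True

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.species not in synth.PRESETS:
            raise ConfigError(
                f"species must be one of {sorted(synth.PRESETS)}, "
                f"got {self.species!r}")
        if self.n_cells < 2:
            raise ConfigError("n_cells must be at least 2 (repair needs a "
                              "donor cohort)")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        for name in ("resample_step", "resample_upscale", "shrink_z",
                     "spine_bin_width", "sim_dt", "slab_soma_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_candidates < 1:
            raise ConfigError("n_candidates must be at least 1")
        if self.z_threshold is not None and self.z_threshold <= 0:
            raise ConfigError("z_threshold must be positive")

    @property
    def preset(self) -> synth.SpeciesPreset:
        return synth.PRESETS[self.species]

    @property
    def effective_z_threshold(self) -> float:
        return (self.z_threshold if self.z_threshold is not None
                else self.preset.cut_z_threshold)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    config.validate()
    preset = config.preset
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    t0 = time.time()
    stage = "setup"
    try:
        # -- stage 1: acquire cells -----------------------------------------
        stage = "generate"
        if config.swc_dir is not None:
            swc_dir = Path(config.swc_dir)
            if not swc_dir.is_dir():
                raise DataError(f"swc_dir does not exist: {swc_dir}")
            files = sorted(swc_dir.glob("*.swc"))
            if not files:
                raise DataError(f"no .swc files in {swc_dir}")
            raw = [(read_swc(f), f.stem) for f in files]
            log.info("loaded %d reconstructions from %s", len(raw), swc_dir)
            spine_tables = [None] * len(raw)
        else:
            cells = synth.generate_cohort(preset, config.n_cells, config.seed,
                                          out_dir=out / "generated",
                                          with_spines=True)
            raw = [(r, f"{preset.name}_{i:03d}")
                   for i, (r, _) in enumerate(cells)]
            spine_tables = [t.spines for _, t in cells]
            log.info("generated %d %s cells (seed %d)", len(raw),
                     preset.name, config.seed)

        # -- stage 2: standardise + resample --------------------------------
        stage = "standardize"
        std_dir = out / "standardized"
        std_dir.mkdir(exist_ok=True)
        standardized = []
        for recon, name in raw:
            s = resample(standardize(recon, shrink_z=config.shrink_z),
                         config.resample_step, config.resample_upscale)
            write_swc(s, std_dir / f"{name}.swc")
            standardized.append((s, name))

        # -- stage 3: slice + repair ----------------------------------------
        stage = "repair"
        zt = config.effective_z_threshold
        rep_dir = out / "repaired"
        rep_dir.mkdir(exist_ok=True)
        rng = np.random.SeedSequence(config.seed).spawn(2)
        slice_rng = np.random.default_rng(rng[0])
        repair_seeds = np.random.default_rng(rng[1]).integers(
            2 ** 31, size=len(standardized))
        sliced = []
        for recon, name in standardized:
            sl, cut_ids = synth.slice_cut(
                recon, soma_depth=config.slab_soma_depth,
                seed=int(slice_rng.integers(2 ** 31)))
            sliced.append((sl, name, cut_ids))
        pool = repair.build_donor_pool([s for s, _, _ in sliced], zt,
                                       preset.diameter_bounds)
        repaired = []
        reports = []
        for (sl, name, cut_ids), rseed in zip(sliced, repair_seeds):
            cand = repair.repair_reconstruction(
                sl, pool, zt, n_candidates=config.n_candidates,
                seed=int(rseed))
            write_swc(cand.recon, rep_dir / f"{name}.swc")
            repaired.append((cand.recon, name))
            reports.append({"cell": name, "n_cuts": len(cand.graft_log),
                            "score": cand.score, "grafts": cand.graft_log})
            log.info("repaired %s: %d grafts, score %.3f", name,
                     len(cand.graft_log), cand.score)
        (rep_dir / "repair_report.json").write_text(
            json.dumps(_round_floats(reports), indent=2,
                       default=_json_default))

        # -- stage 4: morphometry -------------------------------------------
        stage = "morphometry"
        morpho_rows = []
        terminal_diams = []
        terminal_fracs = []
        for recon, name in repaired:
            segs = partition_segments(recon)
            nm = neuron_morphometry(recon, sholl_step=10.0, segments=segs)
            feats = nm.features()
            feats["cell"] = name
            morpho_rows.append(feats)
            term = [s for s in segs if s.is_terminal]
            terminal_diams.extend(s.mean_diameter for s in term)
            tl = sum(s.length for s in term)
            terminal_fracs.append(tl / sum(s.length for s in segs))
        import pandas as pd

        pd.DataFrame(morpho_rows).to_csv(out / "morphometry.csv", index=False)

        # -- stage 5: spines --------------------------------------------------
        stage = "spines"
        if all(t is None for t in spine_tables):
            spine_seed = int(np.random.SeedSequence(
                config.seed + 1).generate_state(1)[0] % (2 ** 31))
            spine_tables = [
                synth.sample_spines(r, preset, seed=spine_seed + i)
                for i, (r, _) in enumerate(repaired)]
        all_spines = pd.concat([t for t in spine_tables if t is not None],
                               ignore_index=True)
        if len(all_spines) < 10:
            raise DataError("too few spines sampled to fit a density model")
        bw = config.spine_bin_width
        dist = all_spines["distance_um"].to_numpy()
        max_x = max(float(r.path_distances().max()) for r, _ in repaired)
        edges = bw * np.arange(int(np.ceil(max_x / bw)) + 1)
        counts, _ = np.histogram(dist, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2
        # dendritic length sampled per bin: node counts × resampling step
        bin_len = np.zeros_like(centers)
        for r, _ in repaired:
            xd = r.path_distances()[r.dendrite_mask]
            h, _ = np.histogram(xd, bins=edges)
            bin_len += h * config.resample_step
        model = spines.fit_spine_density(centers, counts.astype(float),
                                         bin_len)
        geom = spines.spine_geometry_stats(all_spines,
                                           config.spine_bin_width)
        fracs = [spines.expected_spine_counts(r, model).terminal_fraction
                 for r, _ in repaired]

        # -- stage 6: simulation ----------------------------------------------
        stage = "simulate"
        sim_summary = None
        if config.run_simulation:
            passive = cable.PASSIVE_PRESETS[config.species]
            recon0, name0 = repaired[0]

            def f_corr(x):
                return spines.spine_correction(x, preset.spine_model,
                                               preset.f_spines)

            model0 = cable.build_cable_model(recon0, passive,
                                             f_correction=f_corr)
            segs0 = partition_segments(recon0)
            terms = [s for s in segs0 if s.is_terminal]
            longest = max(terms, key=lambda s: s.length)
            tau = cable.measure_tau(model0, dt=config.sim_dt)
            att = cable.epsp_attenuation(model0, longest.index,
                                         dt=config.sim_dt)
            el = cable.electrotonic_lengths(recon0, passive, segs0)
            sim_summary = {
                "cell": name0,
                "tau_ms": tau,
                "tip_epsp_mV": float(att.amplitudes[0]),
                "soma_epsp_mV": att.soma_amplitude,
                "attenuation_ratio": att.soma_amplitude
                / float(att.amplitudes[0]),
                "mean_terminal_electrotonic_L": float(
                    np.mean([e.L for e in el])),
            }
            log.info("simulation: tau=%.2f ms, attenuation=%.3f", tau,
                     sim_summary["attenuation_ratio"])

        summary = {
            "species": config.species,
            "seed": int(config.seed),
            "n_cells": len(repaired),
            "terminal_diameter_um": float(np.mean(terminal_diams)),
            "terminal_length_fraction": float(np.mean(terminal_fracs)),
            "spine_plateau_per_um": model.a,
            "spine_half_rise_um": model.b,
            "mean_spine_area_um2": geom.mean_area,
            "terminal_spine_fraction": float(np.mean(fracs)),
            "repair_mean_score": float(np.mean([r["score"]
                                                for r in reports])),
            "simulation": sim_summary,
        }
        payload = json.dumps(_round_floats(summary), indent=2, sort_keys=True,
                             default=_json_default)
        (out / "summary.json").write_text(payload)
        log.info("pipeline done in %.1f s", time.time() - t0)
        return summary
    except (ConfigError, DataError, NumericalError):
        raise
    except (repair.RepairError, cable.SolverError) as exc:
        raise NumericalError(f"stage {stage!r} failed: {exc}") from exc
    except (ValueError, RuntimeError) as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
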