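"""End-to-end reproducible runs: config, seeding, manifest.

A :class:`RunConfig` describes one run of the simulate -> quantify -> panel
chain.  Every stochastic stage receives a child seed spawned
deterministically from the master seed, configs round-trip through YAML,
and each run writes a manifest listing seeds, package version, the config
hash and a content hash of every output file, so identical configs yield
identical manifests for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import frap as frap_mod
from . import panel as panel_mod
from . import partition as part_mod
from . import simulate as sim
from .io import save_frap_series, write_manifest

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; unknown keys are rejected up front."""

    presets: list[str] = field(default_factory=lambda: ["retentive", "exchanging", "unbound"])
    n_cells: int = 15
    pc_noise: str = "poisson"
    mean_nuclear_intensity: float = 120.0
    frap_t_end: float = 30.0
    frap_interval: float = 1.0
    run_frap: bool = True
    cluster_k: int = 3
    seed: int = 0
    output_dir: str = "run_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def child_seeds(self, n: int) -> list[int]:
        """Deterministic per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> quantify -> panel as configured.

    Per preset: synthesize ``n_cells`` nucleus fields at the preset's
    steady-state partition coefficient, segment and record per-cell PCs,
    optionally run one FRAP simulation and fit the recovery, then assemble
    the construct panel, cluster it, and run the group statistics.  All
    outputs land under ``config.output_dir`` together with a manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.child_seeds(len(config.presets) + 1)
    records: list[part_mod.PartitionRecord] = []
    fit_rows = []
    stage = "simulate"
    try:
        for preset_name, seed in zip(config.presets, seeds):
            stage = f"simulate:{preset_name}"
            params = sim.preset(preset_name, seed=seed)
            c, bound = sim.steady_state(params)
            gt = sim._ground_truth(params, c, bound)
            rng = np.random.default_rng(seed)
            for i in range(config.n_cells):
                fld, gt_i = sim.make_nucleus_field(
                    params,
                    pc_target=gt.pc_true,
                    mean_nuclear_intensity=config.mean_nuclear_intensity,
                    noise=config.pc_noise,
                    rng=rng,
                )
                mode = "protein" if gt.pc_true > 1.5 else "counterstain"
                masks = part_mod.segment_nucleus(fld, mode=mode)
                records.append(
                    part_mod.partition_coefficient(
                        fld,
                        masks,
                        construct_id=preset_name,
                        cell_id=f"{preset_name}_{i:03d}",
                        experiment_id="sim",
                    )
                )
            if config.run_frap:
                stage = f"frap:{preset_name}"
                roi = sim.chromocenter_roi(params, 0)
                if not roi.any():  # unbound preset has no foci; bleach a disk
                    roi = sim.chromocenter_roi(
                        dataclasses.replace(params, chromocenters=sim._DEFAULT_CHROMOCENTERS), 0
                    )
                bleach_params = dataclasses.replace(params, bleach_depth=0.2)
                _, series = sim.simulate_frap(
                    bleach_params,
                    roi,
                    t_end=config.frap_t_end,
                    frame_interval=config.frap_interval,
                    record_frames=False,
                )
                save_frap_series(series, out / f"frap_{preset_name}.csv")
                curve = frap_mod.process_series(series)
                fit = frap_mod.fit_double_exponential(curve)
                fit_rows.append(
                    {
                        "construct_id": preset_name,
                        "recovery_5s": fit.recovery_5s,
                        "recovery_100s": fit.recovery_100s,
                        "mobile_fraction": fit.mobile_fraction,
                        "fit_rss": fit.fit_rss,
                    }
                )

        stage = "panel"
        rec_df = part_mod.records_to_frame(records)
        rec_df.to_csv(out / "pc_records.csv", index=False)
        result = {"records": rec_df}
        if fit_rows:
            fits = pd.DataFrame(fit_rows)
            fits.to_csv(out / "frap_fits.csv", index=False)
            feats = [c for c in ("recovery_5s", "recovery_100s") if fits[c].notna().all()]
            panel = panel_mod.assemble_panel(rec_df, fits)
            features = ("pc", *feats)
            n_usable = int(panel[list(features)].notna().all(axis=1).sum())
            k = min(config.cluster_k, n_usable)
            if k >= 1:
                labeled, _, newick = panel_mod.cluster_panel(panel, k=k, features=features)
                labeled.to_csv(out / "panel.csv", index=False)
                (out / "panel_tree.nwk").write_text(newick + "\n")
                result["panel"] = labeled

        stage = "stats"
        groups = {
            name: g["pc"].to_numpy() for name, g in rec_df.groupby("construct_id")
        }
        if len(groups) >= 2 and all(len(v) >= 3 for v in groups.values()):
            stats = panel_mod.compare_pc(groups)
            (out / "stats.json").write_text(json.dumps(stats, indent=1))
            result["stats"] = stats
    except Exception as exc:  # preserve partial outputs, name the stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest_path = write_manifest(
        out,
        {
            "seed": config.seed,
            "child_seeds": seeds,
            "version": __version__,
            "config_hash": config.config_hash(),
        },
    )
    result["manifest"] = str(manifest_path)
    return result
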