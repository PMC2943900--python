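"""End-to-end bilayer analysis: a model object over a trajectory + topology.

`BilayerAnalysis` is the orchestration surface: construct it from a
trajectory and topology (or a generator preset, or files on disk), call
:meth:`~BilayerAnalysis.fit`, and receive a :class:`BilayerAnalysisResults`
carrying density profiles, region boundaries, the partition coefficient,
flip-flop rates, splay fractions, order parameters, hydration numbers,
aggregate metrics and the blister-theory outputs, each with its uncertainty
where one is defined.  ``summary()`` renders the usual text table;
``save()`` serialises a versioned JSON report plus TSV tables.

Stages run in the natural order: centering → profiles → regions → partition
coefficient → flip-flop → splay → hydration → aggregate → theory.  Any stage
failure is re-raised with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg_mod
from . import conformation, density, flipflop, hydration, theory
from .core import DEFAULT_TIME_SCALE_FACTOR, Topology, Trajectory
from .density import DensityProfile, RegionPartition
from .generator import GeneratorConfig, GroundTruth, generate_trajectory, preset

logger = logging.getLogger("tgblister")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class BilayerAnalysisResults:
    """Fitted analysis results; every numeric field's unit is in its name."""

    metadata: dict
    profiles: dict[str, DensityProfile]
    regions: RegionPartition
    bilayer_geometry: dict
    partition: dict
    flipflop_results: dict[str, flipflop.FlipFlopResult]
    splay_fractions: dict
    popc_intertail_over_threshold_fraction: float
    order_parameters_p2: dict
    hydration_summary: dict
    aggregate: agg_mod.AggregateSummary | None
    theory: dict
    warnings_log: list = field(default_factory=list)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "metadata": self.metadata,
            "region_boundaries_nm": [self.regions.z_lower_boundary,
                                     self.regions.z_upper_boundary],
            "bilayer_geometry": self.bilayer_geometry,
            "partition_coefficient": self.partition,
            "flipflop": {
                sp: {
                    "rate_per_us": r.rate_per_us,
                    "rate_se_per_us": r.rate_se_per_us,
                    "n_events": int(len(r.events)),
                    "analyzed_time_us": r.analyzed_time_us,
                    "per_molecule_rate_per_us": r.per_molecule_rate_per_us,
                } for sp, r in self.flipflop_results.items()},
            "splay_fractions": self.splay_fractions,
            "popc_intertail_over_threshold_fraction":
                self.popc_intertail_over_threshold_fraction,
            "order_parameters_p2": self.order_parameters_p2,
            "hydration": {
                role: {"coordination_number": v["coordination_number"]}
                for role, v in self.hydration_summary.items()
            } if self.hydration_summary else {},
            "theory": self.theory,
            "warnings": self.warnings_log,
        }
        if self.aggregate is not None:
            d["aggregate"] = {
                "mean_diameter_nm": self.aggregate.mean_diameter_nm,
                "se_diameter_nm": self.aggregate.se_diameter_nm,
                "mean_area_fraction": self.aggregate.mean_area_fraction,
                "mean_cluster_count": self.aggregate.mean_cluster_count,
                "exchange_rate_per_us": self.aggregate.exchange_rate_per_us,
                "modal_cluster_count": int(np.bincount(
                    [m.cluster_count for m in self.aggregate.per_frame]
                ).argmax()),
            }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True,
                          default=_json_default, **kw)

    def summary(self) -> str:
        d = self.to_dict()
        md = self.metadata
        lines = [
            "Triolein–POPC bilayer analysis",
            "=" * 34,
            f"frames analysed       : {md['n_frames_analyzed']} "
            f"(discarded first {md['equilibration_discard_us']} µs scaled)",
            f"time scale factor     : {md['time_scale_factor']}",
            f"region boundaries (nm): "
            f"[{self.regions.z_lower_boundary:+.2f}, "
            f"{self.regions.z_upper_boundary:+.2f}]",
            f"bilayer thickness (nm): "
            f"{self.bilayer_geometry['thickness_nm']:.2f} "
            f"± {self.bilayer_geometry['thickness_se_nm']:.3f}",
            f"area per lipid (nm²)  : "
            f"{self.bilayer_geometry['area_per_lipid_nm2']:.3f}",
        ]
        pc = self.partition
        if pc.get("ratio") is not None:
            lines.append(f"partition coeff (mid/interface): "
                         f"{pc['ratio']:.3f} ± {pc['se']:.3f}")
        else:
            lines.append(f"partition coeff       : undefined "
                         f"({pc.get('reason', '')})")
        for sp, r in d["flipflop"].items():
            lines.append(
                f"flip-flop rate {sp:<5} : {r['rate_per_us']:.3f} "
                f"± {r['rate_se_per_us']:.3f} events/µs "
                f"({r['n_events']} events / {r['analyzed_time_us']:.1f} µs)")
        for region, fr in self.splay_fractions.items():
            lines.append(
                f"splay {region:<9}      : " + "  ".join(
                    f"{k}={v:.3f}" for k, v in fr.items()))
        lines.append(f"POPC inter-tail >{md['splay_threshold_deg']:.0f}°  : "
                     f"{self.popc_intertail_over_threshold_fraction:.4f}")
        if self.hydration_summary:
            ns = {r: v["coordination_number"]
                  for r, v in self.hydration_summary.items()}
            lines.append("hydration N (α1, β, α3): "
                         f"{ns.get('GLYC_A1', float('nan')):.2f}, "
                         f"{ns.get('GLYC_B', float('nan')):.2f}, "
                         f"{ns.get('GLYC_A3', float('nan')):.2f}")
        if "aggregate" in d:
            a = d["aggregate"]
            lines.append(
                f"aggregate: modal count {a['modal_cluster_count']}, "
                f"mean diameter {a['mean_diameter_nm']:.2f} nm, "
                f"area fraction {a['mean_area_fraction']:.3f}, "
                f"exchange {a['exchange_rate_per_us']:.2f} /µs")
        t = self.theory
        lines.append(
            f"theory: P = {t['P']:.3f}, 1/H₀ = {t['radius_nm']} nm "
            f"({t['relation_used']} relation)")
        return "\n".join(lines)

    def save(self, out_dir: str | Path, plots: bool = False) -> Path:
        out = Path(out_dir)
        (out / "tables").mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        prof = pd.DataFrame({"z_mid_nm": self.profiles["TO_glycerol"].centers})
        for name, p in self.profiles.items():
            prof[f"density_{name}_per_nm3"] = np.interp(
                prof["z_mid_nm"], p.centers, p.density)
        prof.to_csv(out / "tables" / "density_profiles.tsv", sep="\t",
                    index=False)
        for sp, r in self.flipflop_results.items():
            r.events.to_csv(out / "tables" / f"flipflop_events_{sp}.tsv",
                            sep="\t", index=False)
        if plots:
            self.plot_profiles(out / "profiles.svg")
        return out / "report.json"

    def plot_profiles(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("svg", force=True)
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, p in self.profiles.items():
            ax.plot(p.centers, p.density, label=name)
        for b in (self.regions.z_lower_boundary, self.regions.z_upper_boundary):
            ax.axvline(b, ls="--", color="k", lw=0.8)
        ax.set_xlabel("z (nm)")
        ax.set_ylabel("number density (nm⁻³)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and not np.isfinite(o):
        return str(o)
    return str(o)


class BilayerAnalysis:
    """Full analysis model over a (possibly synthetic) bilayer trajectory.

    Parameters mirror the documented analysis defaults; every default is
    echoed into the report metadata (no silent defaults).
    """

    def __init__(self, trajectory: Trajectory, topology: Topology, *,
                 truth: GroundTruth | None = None,
                 generator_config: GeneratorConfig | None = None,
                 equilibration_discard_us: float = 2.0,
                 bin_width_nm: float = density.DEFAULT_BIN_WIDTH,
                 splay_threshold_deg: float = conformation.DEFAULT_THRESHOLD_DEG,
                 aggregate_cutoff_nm: float = agg_mod.PIPELINE_CUTOFF,
                 aggregate_min_size: int = agg_mod.DEFAULT_MIN_SIZE,
                 hydration_max_frames: int = 100,
                 hydration_r_cut_nm: float = hydration.DEFAULT_R_MAX,
                 theory_params: theory.TheoryParams | None = None):
        self.trajectory = trajectory
        self.topology = topology
        self.truth = truth
        self.generator_config = generator_config
        self.equilibration_discard_us = equilibration_discard_us
        self.bin_width_nm = bin_width_nm
        self.splay_threshold_deg = splay_threshold_deg
        self.aggregate_cutoff_nm = aggregate_cutoff_nm
        self.aggregate_min_size = aggregate_min_size
        self.hydration_max_frames = hydration_max_frames
        self.hydration_r_cut_nm = hydration_r_cut_nm
        self.theory_params = theory_params or theory.TheoryParams(
            gamma_mn_per_m=0.0)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_preset(cls, name: str, seed: int = 0,
                    generator_overrides: dict | None = None,
                    **analysis_kw) -> "BilayerAnalysis":
        cfg = preset(name, seed=seed, **(generator_overrides or {}))
        traj, topo, truth = generate_trajectory(cfg)
        return cls(traj, topo, truth=truth, generator_config=cfg, **analysis_kw)

    @classmethod
    def from_files(cls, gro_path: str | Path,
                   topology_tsv: str | Path | None = None,
                   time_scale_factor: float = DEFAULT_TIME_SCALE_FACTOR,
                   **analysis_kw) -> "BilayerAnalysis":
        from .io import read_gro, read_topology_tsv, topology_from_names
        traj, names = read_gro(gro_path, time_scale_factor=time_scale_factor)
        topo = (read_topology_tsv(topology_tsv) if topology_tsv is not None
                else topology_from_names(names))
        return cls(traj, topo, **analysis_kw)

    # -- fitting ---------------------------------------------------------
    def fit(self) -> BilayerAnalysisResults:
        warnings_log: list[str] = []
        t0 = time.perf_counter()

        def stage(name):
            logger.info("stage %-22s t=%.1fs", name, time.perf_counter() - t0)

        def run_stage(name, fn):
            stage(name)
            try:
                return fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        traj = self.trajectory
        # equilibration discard (scaled time relative to the first frame)
        ts = traj.scaled_times_us
        keep = ts - ts[0] >= self.equilibration_discard_us
        if keep.sum() >= 2:
            traj = Trajectory(traj.positions[keep], traj.boxes[keep],
                              traj.times_ps[keep], traj.time_scale_factor)
        else:
            warnings_log.append(
                "equilibration discard would leave <2 frames; using all frames")
        traj = run_stage("centering",
                         lambda: density.center_frames(traj, self.topology))

        profiles: dict[str, DensityProfile] = {}

        def _profiles():
            profiles["TO_glycerol"] = density.density_profile(
                traj, self.topology, species="TO",
                roles=("GLYC_A1", "GLYC_B", "GLYC_A3"),
                bin_width=self.bin_width_nm)
            profiles["POPC_phosphate"] = density.density_profile(
                traj, self.topology, species="POPC", role="PHOS",
                bin_width=self.bin_width_nm)
            profiles["POPC_glycerol"] = density.density_profile(
                traj, self.topology, species="POPC",
                roles=("GLYC_A1", "GLYC_B"), bin_width=self.bin_width_nm)
            for role in ("GLYC_A1", "GLYC_B", "GLYC_A3"):
                profiles[f"TO_{role}"] = density.density_profile(
                    traj, self.topology, species="TO", role=role,
                    bin_width=self.bin_width_nm)
        run_stage("density_profiles", _profiles)

        regions = run_stage("region_partition", lambda: density.partition_regions(
            profiles["TO_glycerol"], profiles["POPC_phosphate"]))
        geometry = run_stage("bilayer_geometry", lambda: density.bilayer_geometry(
            traj, self.topology, self.bin_width_nm))

        def _partition():
            try:
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    ratio, se, _series = density.partition_coefficient(
                        traj, self.topology, regions)
                return {"ratio": ratio, "se": se,
                        "definition": "time-averaged middle / interfacial "
                                      "TO glycerol-COM occupancy ratio"}
            except ValueError as e:
                return {"ratio": None, "se": None, "reason": str(e),
                        "definition": "time-averaged middle / interfacial "
                                      "TO glycerol-COM occupancy ratio"}
        partition = run_stage("partition_coefficient", _partition)

        def _flip():
            out = {}
            for sp in ("TO", "POPC"):
                out[sp] = flipflop.flipflop_rate(traj, self.topology, regions,
                                                 species=sp)
            return out
        ff = run_stage("flipflop", _flip)

        splay = run_stage("splay", lambda: conformation.splay_fractions_by_region(
            traj, self.topology, regions, self.splay_threshold_deg))
        intertail = run_stage("popc_intertail", lambda:
                              conformation.intertail_angle_fraction(
                                  traj, self.topology, "POPC",
                                  self.splay_threshold_deg))
        op = run_stage("order_parameters", lambda: dict(
            conformation.order_parameters(traj, self.topology)))

        def _hydration():
            if self.topology.indices(role="W").size == 0:
                warnings_log.append("no water beads; hydration skipped")
                return {}
            stride = max(1, traj.n_frames // self.hydration_max_frames)
            _, states = flipflop.region_state_series(traj, self.topology,
                                                     regions, "TO")
            mask = states != 0  # interfacial TO molecule-frames only
            if not mask.any():
                warnings_log.append("no interfacial TO; hydration skipped")
                return {}
            return hydration.glycerol_hydration(
                traj, self.topology, interfacial_mask_by_molecule=mask,
                r_cut=self.hydration_r_cut_nm, frame_stride=stride)
        hyd = run_stage("hydration", _hydration)

        aggregate = run_stage("aggregate", lambda: agg_mod.aggregate_summary(
            traj, self.topology, regions, cutoff=self.aggregate_cutoff_nm,
            min_size=self.aggregate_min_size))

        th = run_stage("theory", lambda: theory.theory_report(
            self.theory_params.v_nm3, self.theory_params.a_nm2,
            self.theory_params.l_nm, self.theory_params.gamma_mn_per_m))

        metadata = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_frames_input": self.trajectory.n_frames,
            "n_frames_analyzed": traj.n_frames,
            "time_scale_factor": traj.time_scale_factor,
            "equilibration_discard_us": self.equilibration_discard_us,
            "bin_width_nm": self.bin_width_nm,
            "splay_threshold_deg": self.splay_threshold_deg,
            "aggregate_cutoff_nm": self.aggregate_cutoff_nm,
            "aggregate_min_size": self.aggregate_min_size,
            "hydration_r_cut_nm": self.hydration_r_cut_nm,
            "n_beads": self.topology.table.shape[0],
        }
        if self.generator_config is not None:
            cfg_json = json.dumps(asdict(self.generator_config), sort_keys=True,
                                  default=_json_default)
            metadata["generator_config"] = json.loads(cfg_json)
            metadata["config_sha256"] = hashlib.sha256(
                cfg_json.encode()).hexdigest()

        return BilayerAnalysisResults(
            metadata=metadata, profiles=profiles, regions=regions,
            bilayer_geometry=geometry, partition=partition,
            flipflop_results=ff, splay_fractions=splay,
            popc_intertail_over_threshold_fraction=intertail,
            order_parameters_p2=op, hydration_summary=hyd,
            aggregate=aggregate, theory=th, warnings_log=warnings_log)


# ---------------------------------------------------------------------------
# config-file driven pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config_path: str | Path) -> BilayerAnalysisResults:
    """Run the full analysis from a YAML config; write report + tables.

    Config keys: either ``preset`` (+ ``seed``, ``generator_overrides``) or
    ``trajectory``/``topology`` paths; optional ``analysis`` overrides
    (constructor keywords of :class:`BilayerAnalysis`), ``out_dir`` (default
    ``./tgblister_run``) and ``plots`` (bool, SVG output).
    """
    import yaml

    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text()) or {}
    out_dir = Path(cfg.get("out_dir", "tgblister_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        analysis_kw = cfg.get("analysis", {}) or {}
        if "preset" in cfg:
            model = BilayerAnalysis.from_preset(
                cfg["preset"], seed=int(cfg.get("seed", 0)),
                generator_overrides=cfg.get("generator_overrides"),
                **analysis_kw)
        elif "trajectory" in cfg:
            model = BilayerAnalysis.from_files(
                cfg["trajectory"], cfg.get("topology"), **analysis_kw)
        else:
            raise ValueError("config must provide either 'preset' or "
                             "'trajectory'")
        results = model.fit()
        results.metadata["config_file"] = str(config_path)
        results.metadata["config_echo"] = cfg
        results.save(out_dir, plots=bool(cfg.get("plots", False)))
        logger.info("report written to %s", out_dir / "report.json")
        return results
    except Exception as e:
        (out_dir / "error.json").write_text(json.dumps(
            {"error": str(e), "type": type(e).__name__}, indent=1))
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
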