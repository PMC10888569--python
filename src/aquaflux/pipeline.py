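"""End-to-end orchestration: simulate → permeation → free energy → pore →
metrics → stats, driven by one YAML config with a single root seed.

Every stage writes tab-separated tables into the output directory and
registers them in ``manifest.json`` together with versions, seeds and the
resolved parameters, so any stage can be re-run from the manifest alone.
Identical config and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from . import io as afio
from . import metrics, profiles, stats, synthetic
from .permeation import PoreCylinder, count_permeations
from .constants import DEFAULT_TEMPERATURE

log = logging.getLogger("aquaflux")

STAGES = ("simulate", "permeation", "fep", "pore", "metrics", "stats")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Structured pipeline configuration (mirrors the YAML keys)."""

    out_dir: str = "aquaflux_out"
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    window_ps: float = 10_000.0
    bin_width: float = 0.5
    cylinder_radius: float = 15.0
    cylinder_half_length: float = 15.0
    stages: tuple = STAGES
    # synthetic mode: named conditions, each a channel-spec override dict
    conditions: dict = field(default_factory=dict)
    channel: dict = field(default_factory=dict)
    assembly: dict = field(default_factory=dict)
    # files mode
    structure: str | None = None
    trajectory: str | None = None
    npa_selection: str | None = None
    water_selection: str | None = None
    chains: list = field(default_factory=list)
    alpha_gate: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @property
    def synthetic_mode(self) -> bool:
        return self.structure is None

    def validate(self) -> None:
        if (self.structure is None) != (self.trajectory is None):
            raise ConfigError("structure and trajectory must be given together")
        if self.structure is not None and (self.conditions or self.channel):
            raise ConfigError(
                "exactly one of input files or a synthetic spec may be present"
            )
        for st in self.stages:
            if st not in STAGES:
                raise ConfigError(f"unknown stage {st!r}")
        if self.synthetic_mode and not self.conditions:
            self.conditions = {"control": {}}

    def channel_spec(self, name: str, seed: int) -> synthetic.ChannelSimSpec:
        params = dict(self.channel)
        params.update(self.conditions.get(name, {}))
        barrier = params.pop("barrier_height", 0.0)
        width = params.pop("barrier_width", 2.0)
        z_max = params.pop("z_max", params.get("z_extent", 20.0))
        if barrier:
            pot = synthetic.gaussian_barrier_potential(barrier, width, z_max=z_max)
        else:
            pot = synthetic.flat_potential(z_max)
        params.setdefault("n_particles", 64)
        params.setdefault("n_frames", 2000)
        params.setdefault("temperature", self.temperature)
        return synthetic.ChannelSimSpec(potential=pot, seed=seed, **params)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hourglass_assembly(cfg: RunConfig, seed: int) -> synthetic.ToyAssembly:
    a = dict(cfg.assembly)
    z_half = a.pop("z_half", 5.0)
    spacing = a.pop("profile_spacing", 0.5)
    r_bulk = a.pop("r_bulk", 4.0)
    r_min = a.pop("r_min", 1.5)
    width = a.pop("waist_width", 2.0)
    z = np.arange(-z_half, z_half + spacing / 2, spacing)
    r = r_bulk - (r_bulk - r_min) * np.exp(-(z**2) / (2 * width**2))
    spec = synthetic.ToyAssemblySpec(cavity_profile=(z, r), seed=seed, **a)
    return synthetic.make_toy_assembly(spec)


class PipelineRun:
    """Executes requested stages and accumulates the provenance manifest."""

    def __init__(self, config: RunConfig, out_dir=None, seed=None):
        self.cfg = config
        if seed is not None:
            self.cfg.seed = seed
        self.out = Path(out_dir if out_dir is not None else self.cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "package": "aquaflux",
            "version": _pkg_version,
            "seed": int(self.cfg.seed),
            "parameters": {
                k: v for k, v in vars(self.cfg).items() if not k.startswith("_")
            },
            "stages": {},
        }
        self._sims: dict[str, synthetic.ChannelSimResult] = {}
        self._window_tables = []

    # -- helpers -----------------------------------------------------------

    def _register(self, stage: str, path: Path) -> None:
        entry = self.manifest["stages"].setdefault(stage, {"outputs": {}})
        entry["outputs"][path.name] = _checksum(path)

    def _cylinder(self) -> PoreCylinder:
        return PoreCylinder(
            center=np.zeros(3),
            radius=self.cfg.cylinder_radius,
            half_length=self.cfg.cylinder_half_length,
        )

    def _preflight_files(self):
        top, frame = afio.read_structure(self.cfg.structure)
        for chain in self.cfg.chains:
            if chain not in top.chain_ids:
                raise ConfigError(
                    f"chain {chain!r} not present in structure "
                    f"(chains: {top.chain_ids})"
                )
        for name, sel in (
            ("npa_selection", self.cfg.npa_selection),
            ("water_selection", self.cfg.water_selection),
        ):
            if sel is not None and top.resolve(sel).size == 0:
                raise ConfigError(f"{name} {sel!r} resolves to no atoms")
        return top, frame

    def _simulate_condition(self, name: str) -> synthetic.ChannelSimResult:
        if name not in self._sims:
            seed = int(self.cfg.seed) + list(self.cfg.conditions).index(name)
            spec = self.cfg.channel_spec(name, seed)
            log.info("simulating condition %s (seed %d)", name, seed)
            self._sims[name] = synthetic.simulate_channel_waters(spec)
        return self._sims[name]

    # -- stages ------------------------------------------------------------

    def stage_simulate(self):
        for name in self.cfg.conditions:
            sim = self._simulate_condition(name)
            pdb_path = self.out / f"{name}_structure.pdb"
            dcd_path = self.out / f"{name}_trajectory.dcd"
            gt_path = self.out / f"{name}_potential.tsv"
            afio.write_structure(pdb_path, sim.trajectory.topology, sim.trajectory[0])
            afio.write_trajectory(dcd_path, sim.trajectory)
            afio.write_table(gt_path, {"z_A": sim.z_grid, "U_kJ_mol": sim.potential})
            for p in (pdb_path, dcd_path, gt_path):
                self._register("simulate", p)

    def _trajectories(self):
        """(name, trajectory, cylinder, water selection) per condition."""
        if self.cfg.synthetic_mode:
            for name in self.cfg.conditions:
                sim = self._simulate_condition(name)
                yield name, sim.production(), self._cylinder(), None
        else:
            top, frame = self._preflight_files()
            traj = afio.read_trajectory(self.cfg.trajectory, top)
            from .permeation import define_pore_cylinder

            cyl = define_pore_cylinder(
                top, frame, self.cfg.npa_selection,
                radius=self.cfg.cylinder_radius,
                half_length=self.cfg.cylinder_half_length,
            )
            yield "input", traj, cyl, self.cfg.water_selection

    def stage_permeation(self):
        for name, traj, cyl, watersel in self._trajectories():
            rec = count_permeations(traj, cyl, watersel, self.cfg.window_ps)
            ev = rec.events_dataframe()
            p1 = self.out / f"{name}_events.tsv"
            afio.write_dataframe(p1, ev)
            p2 = self.out / f"{name}_window_counts.tsv"
            afio.write_table(
                p2,
                {"window": np.arange(rec.n_windows),
                 "count": rec.per_window_counts},
            )
            p3 = self.out / f"{name}_cumulative.tsv"
            afio.write_table(p3, {"time_ps": rec.times, "cumulative": rec.cumulative})
            for p in (p1, p2, p3):
                self._register("permeation", p)
            self._window_tables.append(
                (name, rec.per_window_counts.astype(float))
            )

    def stage_fep(self):
        for name, traj, cyl, watersel in self._trajectories():
            dens = profiles.water_density_profile(traj, cyl, self.cfg.bin_width,
                                                  watersel)
            fep = profiles.free_energy_profile(dens, temperature=self.cfg.temperature)
            path = self.out / f"{name}_fep.tsv"
            afio.write_table(
                path,
                {"z_A": fep.bin_centers,
                 "count": dens.counts,
                 "G_kJ_mol": [None if not np.isfinite(g) else g for g in fep.G]},
            )
            self._register("fep", path)

    def stage_pore(self):
        assembly = _hourglass_assembly(self.cfg, int(self.cfg.seed))
        cyl = PoreCylinder(
            center=np.zeros(3), radius=assembly.spec.cavity_profile[1].max() + 2.0,
            half_length=float(assembly.ring_z.max()),
        )
        prof = profiles.pore_radius_profile(
            assembly.frame, assembly.topology, cyl, seed=int(self.cfg.seed)
        )
        path = self.out / "pore_profile.tsv"
        afio.write_table(
            path,
            {"z_A": prof.axial_positions,
             "radius_A": prof.radius,
             "analytic_A": assembly.analytic_radius(prof.axial_positions)},
        )
        self._register("pore", path)

    def stage_metrics(self):
        assembly = _hourglass_assembly(self.cfg, int(self.cfg.seed))
        transforms = synthetic.random_rigid_transforms(
            200, seed=int(self.cfg.seed) + 101
        )
        pert = synthetic.perturb_trajectory(
            assembly.topology, assembly.frame, transforms,
            noise_sd=0.3, n_frames=200, seed=int(self.cfg.seed) + 202,
        )
        fluct = metrics.rmsf(pert.trajectory)
        p1 = self.out / "metrics_rmsf.tsv"
        afio.write_table(
            p1,
            {"serial": assembly.topology.serial, "rmsf_A": fluct,
             "expected_A": np.full(len(fluct), pert.expected_rmsf)},
        )
        dev = metrics.rmsd_series(pert.trajectory, assembly.frame)
        p2 = self.out / "metrics_rmsd.tsv"
        afio.write_table(p2, {"time_ps": pert.trajectory.times, "rmsd_A": dev})
        for p in (p1, p2):
            self._register("metrics", p)

    def stage_stats(self):
        if not self._window_tables:
            raise ConfigError(
                "stats stage needs permeation observables; run the "
                "permeation stage in the same invocation"
            )
        if len(self._window_tables) < 2:
            raise ConfigError("stats stage needs at least two conditions")
        labels = [name for name, _ in self._window_tables]
        groups = [vals for _, vals in self._window_tables]
        plan = stats.select_test(groups, self.cfg.alpha_gate)
        report = stats.compare_groups(groups, plan, labels=labels)
        path = self.out / "stats_report.json"
        payload = report.to_dict()
        payload["plan"] = {
            "parametric": plan.parametric,
            "test_name": plan.test_name,
            "group_sizes": plan.group_sizes,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        self._register("stats", path)

    def run(self, stages=None):
        stages = tuple(stages or self.cfg.stages)
        for st in stages:
            if st not in STAGES:
                raise ConfigError(f"unknown stage {st!r}")
        if "stats" in stages and "permeation" not in stages:
            raise ConfigError(
                "missing stage dependency: stats requires permeation observables"
            )
        if not self.cfg.synthetic_mode:
            self._preflight_files()  # fail before any outputs are written
        for st in stages:
            log.info("running stage %s", st)
            getattr(self, f"stage_{st}")()
        manifest_path = self.out / "manifest.json"
        manifest_path.write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str)
        )
        return self.manifest


def run_pipeline(config, out_dir=None, seed=None, stages=None) -> dict:
    """Run the pipeline from a RunConfig, a dict, or a YAML path."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    return PipelineRun(config, out_dir=out_dir, seed=seed).run(stages)
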