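"""Run configuration, orchestration, fixtures and file I/O.

A run is described by a TOML document with a mandatory seed; ``run()``
executes the sample -> propagate -> correlate pipeline deterministically and
writes TSV outputs whose headers carry the config hash, so mismatched bundle
members can be detected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from .correlation import (
    classical_wigner_correlation,
    ensemble_moment_series,
    kubo_correlation,
    planetary_correlation,
    radial_distribution,
    spectrum_from_cf,
)
from .dynamics import classical_ensemble
from .errors import ConfigError, InvalidParameterError
from .fk_core import FKProfile, ThermalSystem, solve_effective_frequency
from .potentials import PotentialModel, make_model_potential
from .wigner_sampling import (
    CentroidEnsemble,
    MCMCOptions,
    operator_estimator,
    sample_centroid_ensemble,
    sample_fluctuation_cloud,
    sample_mixed_cloud,
    save_ensemble,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run",
    "fixture_ensembles",
    "config_hash",
    "write_tsv",
    "read_tsv_header",
    "write_xyz",
    "read_xyz",
    "toml_dumps",
]

_METHODS = ("fklpi_standard", "fklpi_planetary", "classical", "fk_cmd")

_SCHEMA = {
    "": {"seed", "method", "system", "potential", "sampling", "propagation",
         "observables", "scan", "sqw", "output_dir"},
    "system": {"beta", "masses", "hbar"},
    "potential": {"name", "params"},
    "sampling": {"n_centroids", "n_planets", "burn_in", "thinning",
                 "n_chains", "step"},
    "propagation": {"dt", "nsteps"},
    "scan": {"x_min", "x_max", "n_points"},
    "sqw": {"q_indices"},
}

_OBSERVABLES = {
    "cf_position_standard", "cf_position_kubo",
    "cf_momentum_standard", "cf_momentum_kubo",
    "cf_velocity_kubo", "x2_t", "gr", "spectrum_position",
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; keeps the raw (defaults-free) mapping so
    parse -> serialize -> parse is the identity."""

    data: dict

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def check(table: dict, name: str):
            allowed = _SCHEMA[name]
            unknown = set(table) - allowed
            if unknown:
                raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{name or 'top level'}]")
        check(data, "")
        for key in ("system", "potential", "sampling", "propagation", "scan", "sqw"):
            if key in data:
                if not isinstance(data[key], dict):
                    raise ConfigError(f"[{key}] must be a table")
                if key != "potential":
                    check(data[key], key)
                else:
                    unknown = set(data[key]) - _SCHEMA["potential"]
                    if unknown:
                        raise ConfigError(f"unknown key(s) {sorted(unknown)} in [potential]")
        if "seed" not in data:
            raise ConfigError("seed is mandatory")
        if not isinstance(data["seed"], int):
            raise ConfigError("seed must be an integer")
        if "method" in data and data["method"] not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}")
        for obs in data.get("observables", []):
            if obs not in _OBSERVABLES:
                raise ConfigError(f"unknown observable '{obs}'")
        for req in ("system", "potential"):
            if req not in data:
                raise ConfigError(f"missing required table [{req}]")
        return cls(data=data)

    @classmethod
    def from_toml(cls, text_or_path) -> "RunConfig":
        if isinstance(text_or_path, (str, Path)) and "\n" not in str(text_or_path) \
                and Path(text_or_path).exists():
            text = Path(text_or_path).read_text()
        else:
            text = str(text_or_path)
        return cls.from_dict(tomllib.loads(text))

    def to_toml(self) -> str:
        return toml_dumps(self.data)

    # accessors with defaults ------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def method(self) -> str:
        return self.data.get("method", "fklpi_standard")

    def system(self) -> ThermalSystem:
        s = self.data["system"]
        return ThermalSystem(beta=float(s["beta"]),
                             masses=np.asarray(s.get("masses", [1.0]), float),
                             hbar=float(s.get("hbar", 1.0)))

    def model(self) -> PotentialModel:
        p = self.data["potential"]
        return make_model_potential(p["name"], p.get("params", {}))

    def mcmc(self) -> MCMCOptions:
        s = self.data.get("sampling", {})
        return MCMCOptions(step=s.get("step"), burn_in=int(s.get("burn_in", 500)),
                           thinning=int(s.get("thinning", 5)),
                           n_chains=int(s.get("n_chains", 10)))

    @property
    def n_centroids(self) -> int:
        return int(self.data.get("sampling", {}).get("n_centroids", 1000))

    @property
    def n_planets(self) -> int:
        return int(self.data.get("sampling", {}).get("n_planets", 4))

    @property
    def dt(self) -> float:
        return float(self.data.get("propagation", {}).get("dt", 0.02))

    @property
    def nsteps(self) -> int:
        return int(self.data.get("propagation", {}).get("nsteps", 200))

    @property
    def observables(self) -> list[str]:
        return list(self.data.get("observables", ["cf_position_standard"]))


def toml_dumps(data: dict, _prefix: str = "") -> str:
    """Minimal TOML emitter for the config subset (scalars, lists, tables)."""
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        if isinstance(v, (float, np.floating)):
            return repr(float(v))
        if isinstance(v, str):
            return json.dumps(v)
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise ConfigError(f"cannot serialize {type(v).__name__} to TOML")

    lines = []
    tables = []
    for k, v in data.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {fmt(v)}")
    out = "\n".join(lines)
    for k, v in tables:
        name = f"{_prefix}{k}"
        out += f"\n\n[{name}]\n" + toml_dumps(v, _prefix=name + ".").lstrip("\n")
    return out


def config_hash(config: RunConfig | dict) -> str:
    data = config.data if isinstance(config, RunConfig) else config
    canon = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# TSV / XYZ I/O
# ---------------------------------------------------------------------------

def write_tsv(path, columns: dict, header_meta: dict) -> None:
    """Columnar TSV with '# key=value' metadata lines and a column header."""
    path = Path(path)
    keys = list(columns)
    arr = np.column_stack([np.asarray(columns[k], dtype=float) for k in keys])
    with path.open("w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(keys) + "\n")
        np.savetxt(fh, arr, delimiter="\t", fmt="%.12g")


def read_tsv_header(path) -> dict:
    meta = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    return meta


def check_bundle_consistency(paths) -> str:
    """All bundle members must carry the same config hash; returns it."""
    hashes = {read_tsv_header(p).get("config_hash") for p in paths}
    if len(hashes) != 1:
        raise ConfigError(f"inconsistent bundle: config hashes {sorted(map(str, hashes))}")
    return hashes.pop()


def write_xyz(path, frames: np.ndarray, box_length: float, element: str = "X") -> None:
    """1D liquid frames (n_frames, N) as XYZ; the comment line carries the box."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    with Path(path).open("w") as fh:
        for frame in frames:
            fh.write(f"{frame.size}\n")
            fh.write(f"box_length={box_length}\n")
            for x in frame:
                fh.write(f"{element} {x:.12g} 0.0 0.0\n")


def read_xyz(path) -> tuple[np.ndarray, float]:
    frames = []
    box = None
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        if "box_length=" in comment:
            box = float(comment.split("box_length=")[1].split()[0])
        coords = [float(lines[i + 2 + j].split()[1]) for j in range(n)]
        frames.append(coords)
        i += 2 + n
    return np.asarray(frames), box


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _sample_classical(model, system, n, mcmc: MCMCOptions, rng) -> CentroidEnsemble:
    """Plain classical Boltzmann sampling (Metropolis on V, Maxwell momenta),
    packaged as a CentroidEnsemble with zero-width planets."""
    beta, M = system.beta, system.mass
    step = mcmc.step or max(1e-3, math.sqrt(1.0 / (beta * M)))
    n_chains = max(1, mcmc.n_chains)
    per_chain = -(-n // n_chains)
    xs = np.empty(n_chains * per_chain)
    cid = np.empty(xs.size, dtype=int)
    for ci in range(n_chains):
        x = 0.0
        v = float(model.v(x))
        st = step
        for it in range(mcmc.burn_in):
            xp = x + st * rng.standard_normal()
            vp = float(model.v(xp))
            if math.log(rng.random() + 1e-300) < -beta * (vp - v):
                x, v = xp, vp
        for k in range(per_chain):
            for _ in range(max(1, mcmc.thinning)):
                xp = x + st * rng.standard_normal()
                vp = float(model.v(xp))
                if math.log(rng.random() + 1e-300) < -beta * (vp - v):
                    x, v = xp, vp
            xs[ci * per_chain + k] = x
            cid[ci * per_chain + k] = ci
    pc = rng.normal(0.0, math.sqrt(M / beta), size=xs.size)
    z = np.zeros_like(xs)
    w1 = np.asarray(model.v(xs), dtype=float)
    return CentroidEnsemble(system, xs, pc, z + 1.0, z, z, z, z, w1,
                            -beta * (pc**2 / (2 * M) + w1), cid)


def run(config: RunConfig, output_dir=None) -> dict:
    """Execute a configured run; returns the result bundle and writes files.

    Deterministic given the seed: a single SeedSequence is split into
    per-stage substreams (sampling, planets, propagation).
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    outdir = Path(output_dir or config.data.get("output_dir", "fklpi_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seeds = np.random.SeedSequence(config.seed).spawn(3)

    method = config.method
    stage = "setup"
    bundle: dict = {"config_hash": chash, "method": method, "outputs": {}}
    try:
        model = config.model()
        system = config.system()
        profile = None
        if model.dimension == 1 and method != "classical":
            stage = "fk_profile"
            lo, hi = _profile_range(model, system, config)
            profile = FKProfile(model, system, lo, hi)
        stage = "sampling"
        if method == "classical":
            ens = _sample_classical(model, system, config.n_centroids,
                                    config.mcmc(),
                                    np.random.default_rng(seeds[0]))
            q0 = np.repeat(ens.xc[:, None], 1, axis=1)
            p0 = np.repeat(ens.pc[:, None], 1, axis=1)
        else:
            ens = sample_centroid_ensemble(model, system, config.n_centroids,
                                           config.mcmc(), seeds[0],
                                           profile=profile)
            if method == "fk_cmd":
                q0 = ens.xc[:, None].copy()
                p0 = ens.pc[:, None].copy()
            else:
                if ens.xc.ndim == 1 and np.any(~(ens.var_p > 0)):
                    q0, p0 = sample_mixed_cloud(ens, config.n_planets, seeds[1])
                else:
                    q0, p0 = sample_fluctuation_cloud(ens, config.n_planets,
                                                      seeds[1])
        stage = "propagation/correlation"
        dt, nsteps = config.dt, config.nsteps
        results = {}
        for obs in config.observables:
            results[obs] = _compute_observable(
                obs, model, system, ens, (q0, p0), dt, nsteps, method, profile)
        stage = "output"
        meta = {"config_hash": chash, "seed": config.seed,
                "version": __version__, "method": method,
                "acceptance_rate": f"{ens.acceptance_rate:.4f}"}
        for obs, res in results.items():
            fn = outdir / f"{obs}.tsv"
            if obs == "gr":
                r, g = res
                write_tsv(fn, {"r": r, "g": g}, meta)
            elif obs == "spectrum_position":
                write_tsv(fn, {"omega": res.omega, "re": res.intensity.real,
                               "im": res.intensity.imag}, meta)
            else:
                write_tsv(fn, {"t": res.times, "re": res.values.real,
                               "im": res.values.imag, "stderr": res.stderr},
                          dict(meta, n_samples=res.n_samples))
            bundle["outputs"][obs] = str(fn)
        save_ensemble(outdir / "ensemble.npz", ens, planets=(q0, p0),
                      meta={"seed": config.seed})
        manifest = {
            "config_hash": chash, "seed": config.seed, "version": __version__,
            "method": method, "acceptance_rate": ens.acceptance_rate,
            "n_centroids": int(ens.n), "n_planets": int(q0.shape[1]),
            "fk_iterations_max": int(profile.iterations.max()) if profile is not None else None,
            "fk_valid_fraction": float(np.mean(profile.valid)) if profile is not None else None,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
        bundle["results"] = results
        return bundle
    except Exception as exc:
        raise type(exc)(f"run failed at stage '{stage}': {exc}") from exc


def _profile_range(model, system, config):
    scan = config.data.get("scan")
    if scan:
        return float(scan["x_min"]), float(scan["x_max"])
    # cover the thermal region around the minima
    xs = np.linspace(-12, 12, 1201)
    v = np.asarray(model.v(xs), dtype=float)
    w = np.exp(-system.beta * (v - v.min()))
    occupied = xs[w > 1e-10]
    pad = 4.0 * math.sqrt(system.hbar**2 * system.beta / (12 * system.mass) + 1.0 / (
        system.beta * system.mass))
    return float(occupied.min() - pad), float(occupied.max() + pad)


def _compute_observable(obs, model, system, ens, planets, dt, nsteps, method,
                        profile):
    planetary = method in ("fklpi_planetary", "fk_cmd")
    if obs.endswith("_standard") and ens.xc.ndim == 1:
        bad = ~(ens.var_p > 0)
        if np.any(bad):
            # the standard-flavor Moyal estimator is undefined on barrier
            # modes; exclude those centroids and report the dropped weight
            logger.warning(
                "excluding %d/%d barrier centroids from %s",
                int(bad.sum()), ens.n, obs)
            q0, p0 = planets
            ens = ens.subset(~bad)
            planets = (q0[~bad], p0[~bad])
    if obs == "x2_t":
        return ensemble_moment_series(
            model, system, ens, planets, dt, nsteps,
            propagator="planetary" if planetary else "classical",
            profile=profile)
    if obs == "gr":
        if model.box_length is None:
            raise InvalidParameterError("gr requires a periodic liquid model")
        q0, _ = planets
        return radial_distribution(q0.reshape(-1, model.dimension)
                                   if model.dimension > 1 else q0,
                                   n_bins=50, box_length=model.box_length)
    if obs == "spectrum_position":
        cf = _compute_observable("cf_position_standard", model, system, ens,
                                 planets, dt, nsteps, method, profile)
        return spectrum_from_cf(cf, window="hann", zero_pad=4)
    kind, flavor = obs.replace("cf_", "").rsplit("_", 1)
    if method == "classical" or (method == "fklpi_standard" and flavor == "kubo"):
        # classical method: bare sampling, A side is the phase variable itself
        if method == "classical":
            est = operator_estimator(kind, "kubo")  # centroid == bare variable
            return classical_wigner_correlation(model, system, est, kind, ens,
                                                planets, dt, nsteps)
        return kubo_correlation(model, system, kind, ens, planets, dt, nsteps,
                                propagator="classical")
    if method == "fklpi_standard":
        return classical_wigner_correlation(model, system, kind, kind, ens,
                                            planets, dt, nsteps)
    if method == "fk_cmd":
        # centroid-only dynamics on W1: Kubo estimator, centroid trajectory
        est = operator_estimator(kind, "kubo")
        return planetary_correlation(model, system, est, kind, ens, planets,
                                     dt, nsteps, profile=profile)
    if flavor == "kubo":
        return kubo_correlation(model, system, kind, ens, planets, dt, nsteps,
                                propagator="planetary", profile=profile)
    return planetary_correlation(model, system, kind, kind, ens, planets, dt,
                                 nsteps, profile=profile)


# ---------------------------------------------------------------------------
# standard fixtures
# ---------------------------------------------------------------------------

def fixture_ensembles(seed: int = 0) -> dict:
    """The standard small test fixtures, regenerated deterministically.

    harmonic at beta in {0.1, 1, 8}; quartic (beta=1); the low-temperature
    double well (beta=8); a parabolic barrier near the momentum-variance
    validity bound (hbar*|Omega|*beta = 0.9*pi); and a 16-particle periodic
    1D Lennard-Jones chain.
    """
    ss = np.random.SeedSequence(seed).spawn(8)
    out = {}
    for i, beta in enumerate((0.1, 1.0, 8.0)):
        model = make_model_potential("harmonic", {"mass": 1.0, "omega": 1.0})
        system = ThermalSystem(beta=beta, masses=[1.0])
        profile = FKProfile(model, system, -8 / math.sqrt(beta), 8 / math.sqrt(beta),
                            n_points=51)
        ens = sample_centroid_ensemble(model, system, 200,
                                       MCMCOptions(burn_in=200, thinning=2),
                                       ss[i], profile=profile)
        out[f"harmonic_beta{beta:g}"] = {
            "model": model, "system": system, "profile": profile, "ensemble": ens}
    model = make_model_potential("quartic", {"c": 1.0})
    system = ThermalSystem(beta=1.0, masses=[1.0])
    res = solve_effective_frequency(model, 0.0, system)
    out["quartic"] = {"model": model, "system": system, "eff": res}
    model = make_model_potential("double_well", {"a": 1.0, "b": 1.0})
    system = ThermalSystem(beta=8.0, masses=[1.0])
    out["double_well"] = {"model": model, "system": system}
    wb = 1.0
    beta_ok = 0.9 * math.pi / wb
    model = make_model_potential("parabolic_barrier", {"mass": 1.0, "omega_b": wb})
    out["parabolic_barrier"] = {
        "model": model,
        "system": ThermalSystem(beta=beta_ok, masses=[1.0]),
        "system_invalid": ThermalSystem(beta=1.1 * math.pi / wb, masses=[1.0]),
    }
    model = make_model_potential("pair_liquid", {
        "n_particles": 16, "box_length": 18.0, "epsilon": 1.0, "sigma": 1.0,
        "mass": 1.0})
    rng = np.random.default_rng(ss[7])
    lattice = np.arange(16) * (18.0 / 16)
    out["pair_liquid"] = {
        "model": model, "system": ThermalSystem(beta=2.0, masses=np.ones(16)),
        "configuration": lattice + 0.05 * rng.standard_normal(16)}
    return out
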