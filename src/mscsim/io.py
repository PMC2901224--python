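"""Readers and writers: CSV result tables, metadata JSON, population
snapshots, HDF5 time series, Newick genealogies.

Internal units are SI; reported units at this boundary are days and the α
scale.  Every output directory is self-describing: a ``metadata.json``
carries the full parameter set, the seed and a run hash, so results can be
reproduced from the metadata alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .ibm import Population
from .master_equation import AlphaHistogram, MfptResult
from .params import DifferentiationParams, params_asdict
from .protocols import RegenerationResult, StemPoolComposition, TransitionTimeResult

__all__ = [
    "write_results",
    "write_metadata",
    "snapshot_dataframe",
    "load_snapshot",
    "write_hdf5_timeseries",
    "population_newick",
    "write_newick",
]


# --------------------------------------------------------------------- #
# snapshots
# --------------------------------------------------------------------- #
SNAPSHOT_COLUMNS = ["id", "parent_id", "founder_id", "founder_alpha0", "alpha",
                    "x_m", "y_m", "volume_m3", "phase", "birth_time_s"]


def snapshot_dataframe(
    pop: Population, diff_params: Optional[DifferentiationParams] = None
) -> pd.DataFrame:
    """Tabular snapshot of a population, one row per cell."""
    return pd.DataFrame({
        "id": pop.ids,
        "parent_id": pop.parent_id,
        "founder_id": pop.founder_id,
        "founder_alpha0": pop.founder_alpha0,
        "alpha": pop.alpha,
        "x_m": pop.pos[:, 0],
        "y_m": pop.pos[:, 1],
        "volume_m3": pop.volume,
        "phase": [pop.phase_of(i, diff_params) for i in range(pop.n)],
        "birth_time_s": pop.birth_time,
    })


def load_snapshot(path, env, t: float = 0.0) -> Population:
    """Rebuild a Population from a snapshot CSV (to resume or reuse)."""
    df = pd.read_csv(path)
    return Population(
        alpha=df["alpha"].to_numpy(),
        positions=df[["x_m", "y_m"]].to_numpy(),
        env=env,
        volume=df["volume_m3"].to_numpy(),
        ids=df["id"].to_numpy(),
        parent_id=df["parent_id"].to_numpy(),
        founder_id=df["founder_id"].to_numpy(),
        founder_alpha0=df["founder_alpha0"].to_numpy(),
        birth_time=df["birth_time_s"].to_numpy(),
        t=t,
    )


def write_hdf5_timeseries(snapshots: Dict[float, pd.DataFrame], path) -> None:
    """One HDF5 group per recorded time, one dataset per snapshot column."""
    import h5py

    with h5py.File(path, "w") as fh:
        for t, df in snapshots.items():
            grp = fh.create_group(f"t_{t:.6f}")
            for col in df.columns:
                data = df[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                grp.create_dataset(col, data=data)


# --------------------------------------------------------------------- #
# genealogies
# --------------------------------------------------------------------- #
def population_newick(pop: Population) -> Dict[int, str]:
    """Newick tree per founder from the division event log.

    Branch lengths are lifetimes in days; node comments carry α at birth and
    (for internal nodes) at division.  Leaves are the cells alive at the
    population clock.
    """
    children: Dict[int, tuple] = {}
    birth: Dict[int, tuple] = {}  # id -> (birth_time_s, alpha_at_birth)
    for t, kind, mother, d1, d2, alpha in pop.events:
        if kind != "division":
            continue
        children[mother] = (t, d1, d2, alpha)
        birth[d1] = (t, alpha)
        birth[d2] = (t, alpha)

    live_alpha = {int(i): float(a) for i, a in zip(pop.ids, pop.alpha)}
    live_birth = {int(i): float(b) for i, b in zip(pop.ids, pop.birth_time)}
    founders = sorted({int(f) for f in pop.founder_id})

    def node(cid: int, a0: float, t0: float) -> str:
        if cid in children:
            t, d1, d2, a_div = children[cid]
            span = (t - t0) / 86400.0
            sub = f"({node(d1, a_div, t)},{node(d2, a_div, t)})"
            return (f"{sub}{cid}:{span:.6f}"
                    f"[&alpha_birth={a0:.4f},alpha_div={a_div:.4f}]")
        t_b = live_birth.get(cid, t0)
        span = (pop.t - t_b) / 86400.0
        a_now = live_alpha.get(cid, a0)
        return f"{cid}:{span:.6f}[&alpha_birth={a0:.4f},alpha_now={a_now:.4f}]"

    trees = {}
    founder_a0 = {int(f): float(a) for f, a in zip(pop.founder_id, pop.founder_alpha0)}
    for f in founders:
        a0 = founder_a0.get(f, birth.get(f, (0.0, np.nan))[1])
        trees[f] = node(f, a0, birth.get(f, (0.0, a0))[0]) + ";"
    return trees


def write_newick(pop: Population, path) -> None:
    """All genealogies, one Newick tree per line (one per founder)."""
    trees = population_newick(pop)
    Path(path).write_text("\n".join(trees[f] for f in sorted(trees)) + "\n")


# --------------------------------------------------------------------- #
# result tables + metadata
# --------------------------------------------------------------------- #
def _run_hash(meta: dict) -> str:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_metadata(out_dir: Path, params_objs: dict, seed: Optional[int],
                   extra: Optional[dict] = None) -> None:
    meta = {name: params_asdict(obj) if hasattr(obj, "__dataclass_fields__")
            else obj for name, obj in params_objs.items()}
    meta["seed"] = seed
    meta["package_version"] = __version__
    meta["run_hash"] = _run_hash(meta)
    meta["written_at_unix"] = time.time()
    if extra:
        meta.update(extra)
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def write_results(result, out_dir, seed: Optional[int] = None,
                  diff_params: Optional[DifferentiationParams] = None,
                  extra_meta: Optional[dict] = None) -> list:
    """Write a protocol result to ``out_dir``; returns the files written.

    Schemas:

    * TransitionTimeResult -> ``transition_times.csv`` with columns
      (target, alpha_bin, mean_days, n_transferred, fraction)
    * RegenerationResult -> ``histogram_timeseries.csv`` (sort, time_days,
      bin_lo, bin_hi, mass) and ``clone_sizes.csv`` (sort, founder_alpha0,
      size)
    * StemPoolComposition -> ``stem_pool.csv`` (founder_bin_lo,
      founder_bin_hi, fraction)
    * MfptResult -> ``mfpt.csv`` (alpha_bin, theta_days)
    * AlphaHistogram -> ``equilibrium.csv`` (alpha_bin, mass)
    * Population -> ``snapshot.csv`` + ``genealogy.nwk``
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(name: str, df: pd.DataFrame):
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    meta_objs: dict = {}
    if isinstance(result, TransitionTimeResult):
        frames = []
        for target in ("stem", "differentiated"):
            mids, means, counts = result.mean_time_per_bin(target)
            n_per_bin = np.histogram(result.initial_alpha, bins=len(mids),
                                     range=(0, 1))[0]
            frames.append(pd.DataFrame({
                "target": target, "alpha_bin": mids, "mean_days": means,
                "n_transferred": counts,
                "fraction": np.where(n_per_bin > 0, counts / np.maximum(n_per_bin, 1), 0.0),
            }))
        _csv("transition_times.csv", pd.concat(frames, ignore_index=True))
        meta_objs = {"differentiation": result.params,
                     "environment": {"pO2_percent": result.env.pO2_percent},
                     "max_days": result.max_days,
                     "n_walkers": int(result.initial_alpha.size)}
    elif isinstance(result, RegenerationResult):
        hrows, crows = [], []
        for sort, s in result.series.items():
            lo, hi = s.bin_edges[:-1], s.bin_edges[1:]
            for t, h in zip(s.times_days, s.histograms):
                for b in range(len(lo)):
                    hrows.append((sort, t, lo[b], hi[b], h[b]))
            for a0, size in zip(s.founder_alpha0, s.clone_sizes):
                crows.append((sort, a0, size))
        _csv("histogram_timeseries.csv",
             pd.DataFrame(hrows, columns=["sort", "time_days", "bin_lo", "bin_hi", "mass"]))
        _csv("clone_sizes.csv",
             pd.DataFrame(crows, columns=["sort", "founder_alpha0", "size"]))
        meta_objs = {"differentiation": result.params, "mechanics": result.mech,
                     "environment": {"pO2_percent": result.env.pO2_percent}}
    elif isinstance(result, StemPoolComposition):
        _csv("stem_pool.csv", pd.DataFrame({
            "founder_bin_lo": result.founder_bin_edges[:-1],
            "founder_bin_hi": result.founder_bin_edges[1:],
            "fraction": result.fractions,
        }))
        meta_objs = {"stem_founder_fraction": result.stem_founder_fraction,
                     "n_pool": result.n_pool, "n_founders": result.n_founders,
                     "duration_days": result.duration_days}
        if result.env is not None:
            meta_objs["environment"] = {"pO2_percent": result.env.pO2_percent}
    elif isinstance(result, MfptResult):
        _csv("mfpt.csv", pd.DataFrame({
            "alpha_bin": result.grid, "theta_days": result.theta_days}))
        meta_objs = {"target": result.target, "computable": result.computable,
                     "diagnostics": result.diagnostics}
    elif isinstance(result, AlphaHistogram):
        _csv("equilibrium.csv", pd.DataFrame({
            "alpha_bin": result.midpoints, "mass": result.masses}))
        meta_objs = {"histogram_meta": result.meta}
    elif isinstance(result, Population):
        _csv("snapshot.csv", snapshot_dataframe(result, diff_params))
        nwk = out_dir / "genealogy.nwk"
        write_newick(result, nwk)
        written.append(nwk)
        meta_objs = {"environment": {"pO2_percent": result.env.pO2_percent},
                     "clock_days": result.t / 86400.0, "n_cells": result.n}
    else:
        raise TypeError(f"do not know how to write a {type(result).__name__}")

    if extra_meta:
        meta_objs.update(extra_meta)
    write_metadata(out_dir, meta_objs, seed)
    written.append(out_dir / "metadata.json")
    return written
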