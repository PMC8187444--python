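"""File formats: spike trains, truth tables, estimates, correlogram stores.

Plain-text formats are the interchange surface (TSV spike times, CSV
tables, YAML configs); a compact ``.npz`` container is offered for
spike trains and correlogram collections produced at run time.
All CSV files use comma separators, a header row, UTF-8 and '.'
decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ccg import Correlogram
from .netsim import GroundTruthNetwork, SpikeTrainSet

__all__ = [
    "write_spike_trains", "read_spike_trains",
    "save_spikes_npz", "load_spikes_npz",
    "write_truth", "read_truth",
    "write_estimates", "read_estimates",
    "save_correlograms", "load_correlograms", "correlograms_to_csv",
    "write_run_config", "read_run_config",
]

ESTIMATE_COLUMNS = ["pre", "post", "z", "connected", "psp_mV"]
GLM_COLUMNS = ["pre", "post", "J", "delay_ms", "two_D", "significant"]


# ---------------------------------------------------------------------------
# spike trains


def write_spike_trains(spikes: SpikeTrainSet, path) -> None:
    """Two-column TSV (unit_id, spike_time_seconds) plus ``.meta.tsv``.

    The sidecar stores per-unit class/group metadata and the recording
    duration (as a commented key=value first line).
    """
    path = Path(path)
    with open(path, "w") as f:
        for uid, train in zip(spikes.unit_ids, spikes.trains):
            for t in train:
                f.write(f"{uid}\t{t:.7f}\n")
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    with open(meta_path, "w") as f:
        f.write(f"# duration_s={spikes.duration!r}\n")
        spikes.meta.to_csv(f, sep="\t", index=False)


def read_spike_trains(path, duration: float | None = None) -> SpikeTrainSet:
    """Read the two-column TSV format; validates ordering per unit.

    Raises a ValueError naming the offending line for negative or
    out-of-order timestamps.  Duration comes from the sidecar metadata
    when present, else from ``duration`` or the last spike time.
    """
    path = Path(path)
    unit_order: list[int] = []
    trains: dict[int, list[float]] = {}
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                uid_s, t_s = line.split("\t")
                uid, t = int(uid_s), float(t_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time {t}")
            if uid not in trains:
                trains[uid] = []
                unit_order.append(uid)
            elif trains[uid] and t <= trains[uid][-1]:
                raise ValueError(
                    f"{path}:{lineno}: out-of-order spike time for unit {uid}")
            trains[uid].append(t)

    meta = None
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    if meta_path.exists():
        with open(meta_path) as f:
            first = f.readline()
            if first.startswith("# duration_s="):
                duration = float(first.split("=", 1)[1])
            meta = pd.read_csv(f, sep="\t")
        unit_order = [int(u) for u in meta["unit_id"]]
        for u in unit_order:
            trains.setdefault(u, [])
    if duration is None:
        duration = max((ts[-1] for ts in trains.values() if ts), default=0.0)
    if not trains:
        import warnings

        warnings.warn(f"{path}: no spikes found", stacklevel=2)
    return SpikeTrainSet(unit_order, [trains[u] for u in unit_order],
                         duration, meta)


def save_spikes_npz(spikes: SpikeTrainSet, path) -> None:
    """Single-file binary container for a whole spike-train set."""
    arrays = {f"train_{uid}": tr
              for uid, tr in zip(spikes.unit_ids, spikes.trains)}
    meta = {
        "unit_ids": [int(u) for u in spikes.unit_ids],
        "duration": spikes.duration,
        "cell_class": list(spikes.meta["cell_class"]),
        "group": [int(g) for g in spikes.meta["group"]],
    }
    np.savez_compressed(path, _meta=json.dumps(meta), **arrays)


def load_spikes_npz(path) -> SpikeTrainSet:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["_meta"]))
        trains = [f[f"train_{u}"] for u in meta["unit_ids"]]
    mdf = pd.DataFrame({"unit_id": meta["unit_ids"],
                        "cell_class": meta["cell_class"],
                        "group": meta["group"]})
    return SpikeTrainSet(meta["unit_ids"], trains, meta["duration"], mdf)


# ---------------------------------------------------------------------------
# tables


def write_truth(truth: GroundTruthNetwork, path) -> None:
    df = truth.table.copy()
    df["psp_mV"] = df["psp_mV"].map(lambda x: f"{x:.6g}")
    df.to_csv(path, index=False)


def read_truth(path, n_units: int | None = None) -> GroundTruthNetwork:
    df = pd.read_csv(path)
    missing = set(GroundTruthNetwork.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if n_units is None:
        n_units = int(max(df["pre"].max(), df["post"].max())) + 1
    return GroundTruthNetwork(df, n_units)


def write_estimates(table: pd.DataFrame, path) -> None:
    """CNN or GLM estimate table with fixed column order."""
    cols = ESTIMATE_COLUMNS if "z" in table.columns else GLM_COLUMNS
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"estimate table missing columns {sorted(missing)}")
    table[cols].to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("connected", "significant"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# correlogram store


def save_correlograms(ccs: list[Correlogram], path) -> None:
    """Store a collection keyed by (ref, tgt) in one ``.npz`` file."""
    arrays = {}
    meta = []
    for k, cc in enumerate(ccs):
        arrays[f"counts_{k}"] = cc.counts
        meta.append({"pair": list(cc.pair), "bin_width": cc.bin_width,
                     "window": cc.window, "trimmed": cc.trimmed,
                     "n_ref": cc.n_ref})
    np.savez_compressed(path, _meta=json.dumps(meta), **arrays)


def load_correlograms(path) -> list[Correlogram]:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["_meta"]))
        out = []
        for k, m in enumerate(meta):
            out.append(Correlogram(f[f"counts_{k}"], m["bin_width"],
                                   m["window"], m["trimmed"], m["n_ref"],
                                   tuple(m["pair"])))
    return out


def correlograms_to_csv(ccs: list[Correlogram], path) -> None:
    """One row per pair: ref, tgt, n_ref, trimmed, then count columns."""
    rows = []
    for cc in ccs:
        row = {"ref": cc.pair[0], "tgt": cc.pair[1], "n_ref": cc.n_ref,
               "trimmed": cc.trimmed}
        row.update({f"bin{k:03d}": int(c) for k, c in enumerate(cc.counts)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configs


def write_run_config(config: dict, path) -> None:
    """Resolved stage configuration + seed, written next to outputs."""
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def read_run_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
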