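"""Plain-text file formats and run configuration.

Duplication-time tables are tab-separated text with ``#key=value`` metadata
lines for the shared study geometry (``T``, ``n0``, ``nT``) followed by a
header row ``replicate_id<TAB>event_index<TAB>time``. Times are written with
17 significant digits so a write/read round trip is lossless. Fit reports,
study summaries and metadata sidecars are JSON; run configuration files are
YAML (or JSON, a YAML subset).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .time_model import Timeline

__all__ = [
    "read_times_table",
    "write_times_table",
    "write_json",
    "write_sidecar",
    "load_config",
    "validate_config",
    "CONFIG_KEYS",
]


class TimesTableError(ValueError):
    """Malformed duplication-time table."""


def write_times_table(
    path, timelines: Sequence[Timeline], extra_metadata: Optional[Dict] = None
) -> None:
    """Write a collection of timelines sharing (T, n0, nT) to TSV."""
    timelines = list(timelines)
    if not timelines:
        raise ValueError("no timelines to write")
    T, n0, nT = timelines[0].T, timelines[0].n0, timelines[0].nT
    for tl in timelines:
        if (tl.T, tl.n0, tl.nT) != (T, n0, nT):
            raise ValueError("all timelines in one table must share (T, n0, nT)")
    lines = [f"#T={T:.17g}", f"#n0={n0}", f"#nT={nT}"]
    for key, val in (extra_metadata or {}).items():
        lines.append(f"#{key}={val}")
    lines.append("replicate_id\tevent_index\ttime")
    for rep, tl in enumerate(timelines):
        for idx, t in zip(range(n0 + 1, nT + 1), tl.times):
            lines.append(f"{rep}\t{idx}\t{t:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_times_table(path) -> List[Timeline]:
    """Read and validate a duplication-time table; one Timeline per replicate."""
    meta: Dict[str, str] = {}
    rows = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise TimesTableError(f"line {lineno}: malformed metadata {line!r}")
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields != ["replicate_id", "event_index", "time"]:
                raise TimesTableError(
                    f"line {lineno}: expected header "
                    f"'replicate_id\\tevent_index\\ttime', got {line!r}"
                )
            header_seen = True
            continue
        if len(fields) != 3:
            raise TimesTableError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        try:
            rows.append((int(fields[0]), int(fields[1]), float(fields[2]), lineno))
        except ValueError:
            raise TimesTableError(f"line {lineno}: unparsable row {line!r}") from None
    for key in ("T", "n0", "nT"):
        if key not in meta:
            raise TimesTableError(f"missing required metadata line '#{key}=...'")
    T, n0, nT = float(meta["T"]), int(meta["n0"]), int(meta["nT"])

    by_rep: Dict[int, List[tuple]] = {}
    for rep, idx, t, lineno in rows:
        if not (0 < t < T):
            raise TimesTableError(
                f"line {lineno}: time {t} outside the open interval (0, T={T})"
            )
        by_rep.setdefault(rep, []).append((idx, t, lineno))
    timelines = []
    for rep in sorted(by_rep):
        entries = sorted(by_rep[rep])
        times = [t for _, t, _ in entries]
        for (e_prev, e_next) in zip(entries, entries[1:]):
            if e_next[1] <= e_prev[1]:
                raise TimesTableError(
                    f"line {e_next[2]}: times not strictly increasing in "
                    f"replicate {rep}"
                )
        if len(times) != nT - n0:
            raise TimesTableError(
                f"replicate {rep}: expected {nT - n0} events, found {len(times)}"
            )
        timelines.append(Timeline(T=T, n0=n0, nT=nT, times=np.array(times)))
    return timelines


# ---------------------------------------------------------------------------
# JSON reports and sidecars
# ---------------------------------------------------------------------------
def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, payload: Dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def write_sidecar(out_path, resolved_config: Dict, seed: Optional[int]) -> None:
    """Write the JSON metadata sidecar next to an output file.

    The sidecar records everything needed to regenerate the output exactly:
    the fully resolved configuration, the package version, and the seed.
    """
    from . import __version__

    write_json(
        str(out_path) + ".meta.json",
        {"config": resolved_config, "version": __version__, "seed": seed},
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------
CONFIG_KEYS = {
    "mechanism": str,
    "model": str,
    "lambda": float,
    "mu": float,
    "alpha": float,
    "gamma": float,
    "T": float,
    "n0": int,
    "nT": int,
    "reps": int,
    "seed": int,
    "out": str,
    "sample_sizes": list,
    "phi_grid_size": int,
}


def validate_config(cfg: Dict) -> Dict:
    """Type-check a configuration mapping; unknown keys are rejected."""
    unknown = set(cfg) - set(CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = {}
    for key, val in cfg.items():
        typ = CONFIG_KEYS[key]
        try:
            out[key] = typ(val) if not isinstance(val, typ) else val
        except (TypeError, ValueError):
            raise ValueError(f"config key {key!r}: cannot coerce {val!r} to {typ.__name__}")
    return out


def load_config(path) -> Dict:
    """Load and validate a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return validate_config(cfg)
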