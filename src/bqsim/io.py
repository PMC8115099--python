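"""Readers/writers: snapshots, event logs, time series, run manifests.

Everything is plain text.  A snapshot is a single sectioned file holding
the genotype grid, biomass grid and the four concentration fields as CSV
blocks with a small key-value header; floats are written with ``repr``
precision so a round trip is lossless.  Event logs and time series are
TSV with a header line.  The run manifest is JSON carrying the resolved
configuration, seeds and output checksums, sufficient to re-run the
simulation bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes as gt
from .config import SimConfig
from .engine import LatticeState
from .lineage import EVENT_COLUMNS

SNAPSHOT_MAGIC = "# bqsim-snapshot v1"
_SECTIONS = ("genotype", "biomass", "substrate", "good1", "good2", "good3")


class SnapshotError(IOError):
    """Corrupt or incompatible snapshot file."""


def write_snapshot(state: LatticeState, path: str | Path) -> None:
    """Write a lattice state as one sectioned text file (lossless)."""
    state.validate()
    lines = [SNAPSHOT_MAGIC,
             f"# L: {state.L}",
             f"# step: {state.step}",
             "# layout: 0-based (row, col), row-major, periodic boundaries"]
    grids = (state.genotype, state.biomass, state.substrate,
             state.goods[0], state.goods[1], state.goods[2])
    for name, grid in zip(_SECTIONS, grids):
        lines.append(f"[{name}]")
        if grid.dtype.kind in "iu" or name == "genotype":
            lines.extend(",".join(str(int(v)) for v in row) for row in grid)
        else:
            lines.extend(",".join(repr(float(v)) for v in row) for row in grid)
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path: str | Path) -> LatticeState:
    """Read a snapshot written by :func:`write_snapshot`."""
    text = Path(path).read_text().splitlines()
    if not text or text[0] != SNAPSHOT_MAGIC:
        raise SnapshotError(
            f"{path}: not a bqsim snapshot (expected header {SNAPSHOT_MAGIC!r})")
    header = {}
    i = 1
    while i < len(text) and text[i].startswith("# "):
        if ":" in text[i]:
            key, _, val = text[i][2:].partition(":")
            header[key.strip()] = val.strip()
        i += 1
    try:
        L = int(header["L"])
        step = int(header["step"])
    except (KeyError, ValueError) as exc:
        raise SnapshotError(f"{path}: bad header: {exc}") from exc
    blocks: dict[str, np.ndarray] = {}
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        if not (line.startswith("[") and line.endswith("]")):
            raise SnapshotError(f"{path}: expected section at line {i + 1}")
        name = line[1:-1]
        if name not in _SECTIONS:
            raise SnapshotError(f"{path}: unknown section {name!r}")
        rows = text[i + 1:i + 1 + L]
        if len(rows) != L:
            raise SnapshotError(f"{path}: truncated section {name!r}")
        blocks[name] = np.array(
            [[float(v) for v in row.split(",")] for row in rows])
        i += 1 + L
    missing = set(_SECTIONS) - set(blocks)
    if missing:
        raise SnapshotError(f"{path}: missing sections {sorted(missing)}")
    state = LatticeState(
        genotype=blocks["genotype"].astype(np.int8),
        biomass=blocks["biomass"],
        substrate=blocks["substrate"],
        goods=np.stack([blocks["good1"], blocks["good2"], blocks["good3"]]),
        step=step,
    )
    state.validate()
    return state


def write_events(events, path: str | Path) -> None:
    """Event log as TSV with genotype bit-string labels."""
    df = events if isinstance(events, pd.DataFrame) else pd.DataFrame(
        events, columns=EVENT_COLUMNS)
    out = df.copy()
    out["genotype"] = out["genotype"].map(
        lambda g: gt.compact_label(int(g)) if int(g) >= 0 else "-")
    out["parent_genotype"] = out["parent_genotype"].map(
        lambda g: gt.compact_label(int(g)) if int(g) >= 0 else "-")
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str,
                                            "parent_genotype": str})
    _check_complete_lines(path)
    for col in ("genotype", "parent_genotype"):
        df[col] = df[col].map(
            lambda s: gt.parse_label(s) if s != "-" else gt.EMPTY)
    return df[EVENT_COLUMNS]


def write_timeseries(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


class TimeseriesWriter:
    """Append-safe TSV time-series writer with a fixed schema header.

    Rows are flushed line by line, so an interrupted run leaves at worst
    one truncated final line, which :func:`read_timeseries` detects.
    Intended cadence use: append every ``every`` steps starting at step 0,
    so ``n_steps`` steps at cadence ``c`` yield ``n_steps // c + 1`` rows.
    """

    def __init__(self, path: str | Path, columns: list[str]):
        self.columns = list(columns)
        self._fh = open(path, "w")
        self._fh.write("\t".join(self.columns) + "\n")
        self._fh.flush()

    def append(self, row: dict) -> None:
        missing = set(self.columns) - set(row)
        if missing:
            raise ValueError(f"row missing columns {sorted(missing)}")
        self._fh.write("\t".join(str(row[c]) for c in self.columns) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "TimeseriesWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_timeseries(path: str | Path) -> pd.DataFrame:
    _check_complete_lines(path)
    return pd.read_csv(path, sep="\t")


def _check_complete_lines(path: str | Path) -> None:
    """Detect a truncated final line (interrupted append)."""
    data = Path(path).read_bytes()
    if data and not data.endswith(b"\n"):
        raise IOError(f"{path}: truncated final line (missing newline)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest:
    """Provenance record written next to every run's outputs."""

    def __init__(self, config: SimConfig, seed: int,
                 scale_factor: float = 1.0, protocol: str = "run"):
        from . import __version__

        self.data = {
            "bqsim_version": __version__,
            "protocol": protocol,
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "seed": int(seed),
            "scale_factor": float(scale_factor),
            "outputs": {},
            "finalized": False,
        }

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.data["outputs"][p.name] = _sha256(p)

    def finalize(self) -> None:
        self.data["finalized"] = True

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, sort_keys=True)
                              + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        obj = cls.__new__(cls)
        obj.data = json.loads(Path(path).read_text())
        return obj

    def verify_outputs(self, directory: str | Path) -> bool:
        d = Path(directory)
        return all(_sha256(d / name) == digest
                   for name, digest in self.data["outputs"].items())
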