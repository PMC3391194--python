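"""Readers and writers for the package's plain-text and image formats.

Formats:
    progress curve   TSV, columns time_min, signal
    FRAP trace       TSV, columns time_s, intensity; ``# n_pre=`` and
                     ``# n_bleach=`` header comments
    expression       TSV, probe_id plus one column per sample named
                     ``<condition>_<replicate>`` (e.g. ``h_2``)
    gene sets        GMT (name, description, tab-separated member ids)
    gene lists       one id per line
    images           8-bit grayscale TIFF or PNG
    results/truth    JSON
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from sirtflow.frap import FrapTrace
from sirtflow.kinetics import ProgressCurve
from sirtflow.simulate import RegulonDB

__all__ = [
    "write_progress_curve", "read_progress_curve",
    "write_frap_trace", "read_frap_trace",
    "write_expression", "read_expression",
    "write_gmt", "read_gmt",
    "write_gene_list", "read_gene_list",
    "write_image", "read_image",
    "write_json", "read_json",
]


class GmtParseError(ValueError):
    """Malformed GMT input (reports the offending line number)."""


def write_progress_curve(curve: ProgressCurve, path: str | Path) -> None:
    df = pd.DataFrame({"time_min": curve.times, "signal": curve.signals})
    with open(path, "w") as fh:
        fh.write(f"# enzyme_conc={curve.enzyme_conc}\t s_pep={curve.s_pep}"
                 f"\t s_nad={curve.s_nad}\t converted={int(curve.converted)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_progress_curve(path: str | Path) -> ProgressCurve:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("progress-curve TSV must start with a '# key=value' header line")
        for tok in first[1:].split("\t"):
            key, _, val = tok.strip().partition("=")
            meta[key] = val
        df = pd.read_csv(fh, sep="\t")
    return ProgressCurve(
        times=df["time_min"].to_numpy(),
        signals=df["signal"].to_numpy(),
        enzyme_conc=float(meta["enzyme_conc"]),
        s_pep=float(meta["s_pep"]),
        s_nad=float(meta["s_nad"]),
        converted=bool(int(meta.get("converted", "0"))),
    )


def write_frap_trace(trace: FrapTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_pre={trace.n_pre}\n# n_bleach={trace.n_bleach}\n")
        pd.DataFrame({"time_s": trace.times_s, "intensity": trace.intensities}).to_csv(
            fh, sep="\t", index=False
        )


def read_frap_trace(path: str | Path) -> FrapTrace:
    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = int(val)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[body_start:])), sep="\t")
    return FrapTrace(
        times_s=df["time_s"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        n_pre=meta["n_pre"],
        n_bleach=meta["n_bleach"],
    )


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            genes = "\t".join(sorted(members))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file into {set name: member set}.

    Each line needs at least three tab-separated fields (name, description,
    one or more member ids); duplicate set names are an error.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise GmtParseError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return sets


def read_gmt_db(path: str | Path, universe_n: int) -> RegulonDB:
    """GMT file as a regulon database over an explicitly-sized universe."""
    return RegulonDB(universe_n=universe_n, regulons=dict(read_gmt(path)))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> frozenset[str]:
    return frozenset(line.strip() for line in Path(path).read_text().splitlines() if line.strip())


def write_image(image: np.ndarray, path: str | Path) -> None:
    if image.dtype != np.uint8:
        raise ValueError("images are stored 8-bit; convert to uint8 first")
    iio.imwrite(Path(path), image)


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim != 2:
        raise ValueError("expected a single-channel (grayscale) image")
    return np.asarray(img, dtype=np.uint8)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
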