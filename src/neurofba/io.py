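"""Readers and writers for model documents, samples and reports.

Model documents are JSON (lossless round-trip of the dialect shipped in
``data/brain_model.json``).  Sample archives are gzip-compressed CSV
matrices (one column per flux) with a JSON metadata sidecar carrying the
scenario, seed, burn-in, thinning and model hash.  Reports are written as
both JSON and TSV.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import DensityCurve, ReportTable
from .catalog import ModelError
from .sampler import FluxSample


def model_hash(document: dict) -> str:
    """Stable content hash of a model document."""
    blob = json.dumps(document, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_model(document: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(document, indent=1, sort_keys=True) + "\n")


def read_model(path: str | Path) -> dict:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"{path}: malformed model document: {exc}") from None
    for section in ("compartments", "reactions", "transports"):
        if section not in doc:
            raise ModelError(f"{path}: missing section {section!r}")
    return doc


def write_sample(sample: FluxSample, path: str | Path) -> None:
    """Write a sample archive: <path>.csv.gz plus <path>.meta.json."""
    path = Path(path)
    frame = pd.DataFrame(sample.vectors, columns=sample.flux_index)
    # fixed mtime keeps equal-seed archives byte-identical
    with open(path.with_suffix(".csv.gz"), "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            import io as _io

            with _io.TextIOWrapper(gz, encoding="utf-8", newline="") as fh:
                frame.to_csv(fh, index=False, float_format="%.10g")
    meta = dict(sample.meta)
    meta["flux_index"] = sample.flux_index
    meta["shape"] = list(sample.vectors.shape)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def read_sample(path: str | Path) -> FluxSample:
    path = Path(path)
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise ModelError(f"missing sample metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    with gzip.open(path.with_suffix(".csv.gz"), "rt") as fh:
        frame = pd.read_csv(fh)
    flux_index = meta.pop("flux_index")
    shape = meta.pop("shape", None)
    if list(frame.columns) != flux_index:
        raise ModelError(f"{path}: column labels disagree with sidecar flux index")
    vectors = frame.to_numpy(dtype=float)
    if shape is not None and list(vectors.shape) != shape:
        raise ModelError(
            f"{path}: truncated sample archive: shape {list(vectors.shape)} "
            f"!= recorded {shape}"
        )
    return FluxSample(vectors=vectors, flux_index=flux_index, meta=meta)


def write_report(report: ReportTable, path: str | Path) -> None:
    """Write a report as <path>.json and <path>.tsv."""
    path = Path(path)
    path.with_suffix(".json").write_text(
        json.dumps(report.to_dict(), indent=1) + "\n"
    )
    lines = ["entry\tvalue\tunit"]
    for name, value in report.entries.items():
        lines.append(f"{name}\t{value:.6g}\t{report.units.get(name, '')}")
    path.with_suffix(".tsv").write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> ReportTable:
    data = json.loads(Path(path).with_suffix(".json").read_text())
    return ReportTable(
        title=data["title"],
        entries=data["entries"],
        units=data["units"],
        provenance=data.get("provenance", {}),
    )


def write_density_curve(curve: DensityCurve, path: str | Path) -> None:
    """Two-column TSV (grid, density) with a comment header."""
    path = Path(path)
    header = (
        f"# flux\t{curve.flux_id}\n# bandwidth\t{curve.bandwidth:.6g}\n"
        f"# mean\t{curve.mean_marker:.6g}\n"
    )
    body = "\n".join(
        f"{g:.8g}\t{d:.8g}" for g, d in zip(curve.grid, curve.density)
    )
    path.write_text(header + "grid\tdensity\n" + body + "\n")


def write_mean_table(
    mean: np.ndarray, spread: dict, flux_index: list[str], path: str | Path
) -> None:
    frame = pd.DataFrame(
        {
            "flux": flux_index,
            "mean": mean,
            "sd": spread["sd"],
            "lower": spread["lower"],
            "upper": spread["upper"],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
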