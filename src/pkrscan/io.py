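"""Plain-text readers/writers for every artifact the toolkit produces.

Formats are deliberately boring: TSV for traces and ground truth, CSV for
gel lanes, BED6 / bedGraph (UCSC dialect, 0-based half-open) for features
and coverage, FASTA for sequences, JSON for fit results and run manifests.
Every reader validates structure and reports the offending line; every
writer/reader pair round-trips bit-exactly for values printed at full repr
precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .emsa import GelLane
from .fret_sim import (FluorescenceTrace, GroundTruthTrajectory,
                       SimulationConfig)
from .genomics import CoverageTrack, RepeatFeature

__all__ = [
    "write_trace", "read_trace",
    "write_ground_truth",
    "write_lanes", "read_lanes",
    "write_bed", "read_bed",
    "write_bedgraph", "read_bedgraph",
    "write_fasta", "read_fasta",
    "write_json", "read_json",
    "write_manifest", "file_sha256",
]


def write_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    """Trace TSV (frame_index, time_s, donor, acceptor) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "frame_index": np.arange(trace.times.size),
        "time_s": [repr(float(t)) for t in trace.times],
        "donor": [repr(float(v)) for v in trace.donor],
        "acceptor": [repr(float(v)) for v in trace.acceptor],
    })
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = dict(trace.metadata)
    meta["frame_interval"] = trace.frame_interval
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_trace(path: str | Path) -> FluorescenceTrace:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: malformed trace TSV: {exc}") from exc
    for col in ("frame_index", "time_s", "donor", "acceptor"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    times = df["time_s"].to_numpy(dtype=float)
    dt = meta.get("frame_interval",
                  float(times[1] - times[0]) if times.size > 1 else 1.0)
    return FluorescenceTrace(times=times,
                             donor=df["donor"].to_numpy(dtype=float),
                             acceptor=df["acceptor"].to_numpy(dtype=float),
                             frame_interval=dt, metadata=meta)


def write_ground_truth(truth: GroundTruthTrajectory, path: str | Path) -> None:
    """Parallel truth TSV: frame_index, bound, position_bp (NaN unbound)."""
    df = pd.DataFrame({
        "frame_index": np.arange(truth.n_frames),
        "bound": truth.bound.astype(int),
        "position_bp": truth.position,
    })
    if truth.pact_bound is not None:
        df["pact_bound"] = truth.pact_bound.astype(int)
        df["pact_position_bp"] = truth.pact_position
    df.to_csv(path, sep="\t", index=False)


def write_lanes(lanes: Sequence[GelLane], path: str | Path) -> None:
    """Gel lanes as CSV: conc_nM, I0..In."""
    n_sites = lanes[0].n_sites
    rows = []
    for lane in lanes:
        if lane.n_sites != n_sites:
            raise ValueError("lanes must share a site count")
        row = {"conc_nM": repr(lane.protein_conc)}
        row.update({f"I{i}": repr(float(v))
                    for i, v in enumerate(lane.band_intensities)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lanes(path: str | Path) -> list[GelLane]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "conc_nM" not in df.columns:
        raise ValueError(f"{path}: missing 'conc_nM' column")
    bands = sorted((c for c in df.columns if c.startswith("I")),
                   key=lambda c: int(c[1:]))
    if len(bands) < 2:
        raise ValueError(f"{path}: need band columns I0..In")
    return [GelLane(protein_conc=float(r["conc_nM"]),
                    band_intensities=tuple(float(r[b]) for b in bands))
            for _, r in df.iterrows()]


def write_bed(features: Sequence[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t"
                     f"{f.name or f.family}\t0\t{f.strand}\n")


def read_bed(path: str | Path, family_from_name: bool = True
             ) -> list[RepeatFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, "
                                 f"got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} >= "
                                 f"end {end_i}")
            family = name.split("_")[0] if family_from_name else name
            feats.append(RepeatFeature(chrom=chrom, start=start_i, end=end_i,
                                       strand=strand, family=family,
                                       name=name))
    return feats


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph "
                                 f"fields, got {len(parts)}")
            chrom, s, e, v = parts
            try:
                rec = (chrom, int(s), int(e), float(v))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            if rec[1] >= rec[2]:
                raise ValueError(f"{path}:{lineno}: start >= end")
            intervals.append(rec)
    try:
        return CoverageTrack(intervals=intervals)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc} "
                         "(hint: sort -k1,1 -k2,2n)") from exc


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path,
                   subcommand: str,
                   parameters: dict,
                   seed: Optional[int],
                   outputs: Sequence[str | Path]) -> Path:
    """Run manifest: parameters, seed, package version, output hashes."""
    from . import __version__
    out_dir = Path(out_dir)
    manifest = {
        "subcommand": subcommand,
        "parameters": parameters,
        "seed": seed,
        "package_version": __version__,
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path


def config_from_dict(d: dict) -> SimulationConfig:
    """Rebuild a SimulationConfig from a sidecar/config mapping."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    return SimulationConfig(**{k: v for k, v in d.items() if k in fields})
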