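"""File I/O for the standard interchange formats of the pipeline.

* TPS landmark files (LM / CURVES / POINTS / ID records) and long-format
  CSV point lists for outlines,
* TIFF stacks with a JSON sidecar (voxel size, label semantics) for
  voxel volumes,
* TSV read sets (read_id, ref_start_0based, strand, sequence), optional
  SAM via pysam, and FASTA references via Biopython,
* CSV measurement tables.

Calibration-curve I/O lives in :mod:`paleocanid.radiocarbon`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .damage import ReadSet
from .microct import GrayVolume, LabelVolume
from .outline import Outline2D


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def write_tps(outlines: list[Outline2D], path: str | Path) -> None:
    """Write outlines as a TPS file.

    Each specimen is stored as LM=2 (the two anchors) followed by a
    single CURVES=1 record holding the full outline point list, with the
    specimen id in the ID field and the group in a COMMENT field.
    """
    with open(path, "w") as fh:
        for o in outlines:
            a1, a2 = o.anchors
            fh.write("LM=2\n")
            for idx in (a1, a2):
                fh.write(f"{o.points[idx, 0]:.6f} {o.points[idx, 1]:.6f}\n")
            fh.write("CURVES=1\n")
            fh.write(f"POINTS={len(o.points)}\n")
            for x, y in o.points:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={o.specimen_id}\n")
            fh.write(f"COMMENT=group:{o.group} anchors:{a1},{a2}\n")


def read_tps(path: str | Path) -> list[Outline2D]:
    """Read a TPS file written by :func:`write_tps`.

    Files from other digitising software are accepted as long as each
    specimen carries one curve; anchors default to the first point and the
    point nearest the first landmark pair if the COMMENT record is absent.
    """
    outlines: list[Outline2D] = []
    lm: list[list[float]] = []
    curve: list[list[float]] = []
    sid = ""
    group = "unknown"
    anchors: tuple[int, int] | None = None

    def flush():
        nonlocal lm, curve, sid, group, anchors
        if curve:
            pts = np.array(curve)
            if anchors is None:
                if len(lm) >= 2:
                    d1 = np.linalg.norm(pts - np.array(lm[0]), axis=1)
                    d2 = np.linalg.norm(pts - np.array(lm[1]), axis=1)
                    anchors = (int(d1.argmin()), int(d2.argmin()))
                else:
                    anchors = (0, len(pts) // 2)
            outlines.append(
                Outline2D(points=pts, anchors=anchors, specimen_id=sid, group=group)
            )
        lm, curve, sid, group, anchors = [], [], "", "unknown", None

    state = None
    expect = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM="):
                flush()
                state = "lm"
                expect = int(line.split("=")[1])
                continue
            if up.startswith("CURVES="):
                state = None
                continue
            if up.startswith("POINTS="):
                state = "curve"
                expect = int(line.split("=")[1])
                continue
            if up.startswith("ID="):
                sid = line.split("=", 1)[1].strip()
                continue
            if up.startswith("COMMENT="):
                body = line.split("=", 1)[1]
                for tok in body.split():
                    if tok.startswith("group:"):
                        group = tok.split(":", 1)[1]
                    elif tok.startswith("anchors:"):
                        a = tok.split(":", 1)[1].split(",")
                        anchors = (int(a[0]), int(a[1]))
                continue
            if up.startswith("IMAGE=") or up.startswith("SCALE="):
                continue
            if state in ("lm", "curve") and expect > 0:
                xy = [float(v) for v in line.split()[:2]]
                (lm if state == "lm" else curve).append(xy)
                expect -= 1
    flush()
    return outlines


# ---------------------------------------------------------------------------
# outline CSV
# ---------------------------------------------------------------------------

def write_outlines_csv(outlines: list[Outline2D], path: str | Path) -> None:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.points):
            rows.append(
                {
                    "specimen_id": o.specimen_id,
                    "group": o.group,
                    "point": i,
                    "is_anchor": int(i in o.anchors),
                    "x": x,
                    "y": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_outlines_csv(path: str | Path) -> list[Outline2D]:
    df = pd.read_csv(path)
    out = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        sub = sub.sort_values("point")
        anchors = tuple(sub.loc[sub["is_anchor"] == 1, "point"].astype(int))[:2]
        out.append(
            Outline2D(
                points=sub[["x", "y"]].to_numpy(),
                anchors=anchors,
                specimen_id=str(sid),
                group=str(sub["group"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# volumes (TIFF stack + JSON sidecar)
# ---------------------------------------------------------------------------

def save_volume(vol: LabelVolume | GrayVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(vol.data))
    meta: dict = {"voxel_mm": vol.voxel_mm}
    if isinstance(vol, LabelVolume):
        meta["semantics"] = {str(k): v for k, v in vol.semantics.items()}
        meta["kind"] = "labels"
    else:
        meta["kind"] = "gray"
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_volume(path: str | Path) -> LabelVolume | GrayVolume:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta.get("kind") == "labels":
        semantics = {int(k): v for k, v in meta["semantics"].items()}
        return LabelVolume(data, meta["voxel_mm"], semantics)
    return GrayVolume(data, meta["voxel_mm"])


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def write_reads_tsv(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_start_0based\tstrand\tsequence\n")
        for i in range(reads.n_reads):
            fh.write(
                f"{reads.ids[i]}\t{reads.starts[i]}\t{reads.strands[i]}\t"
                f"{reads.seqs[i]}\n"
            )


def read_reads_tsv(path: str | Path, reference: str, min_len: int = 30) -> ReadSet:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    return ReadSet(
        reference=reference,
        ids=df["read_id"].astype(str).tolist(),
        starts=df["ref_start_0based"].to_numpy(),
        strands=df["strand"].to_numpy(),
        seqs=df["sequence"].tolist(),
        min_len=min_len,
    )


def write_reads_sam(reads: ReadSet, path: str | Path, ref_name: str = "ref") -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_name, "LN": len(reads.reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i in range(reads.n_reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = reads.ids[i]
            seq = reads.seqs[i]
            a.flag = 16 if reads.strands[i] == "-" else 0
            # SAM stores the sequence on the forward reference strand
            from .damage import revcomp as _rc

            a.query_sequence = _rc(seq) if reads.strands[i] == "-" else seq
            a.reference_id = 0
            a.reference_start = int(reads.starts[i])
            a.mapping_quality = 37
            a.cigarstring = f"{len(seq)}M"
            fh.write(a)


def read_reads_sam(path: str | Path, reference: str, min_len: int = 30) -> ReadSet:
    """Ingest a SAM file of end-to-end alignments.

    Reverse-strand records are flipped back to sequencing orientation so
    that terminal damage positions refer to the molecule's own ends.
    """
    import pysam

    from .damage import revcomp as _rc

    ids, starts, strands, seqs = [], [], [], []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            ids.append(a.query_name)
            starts.append(a.reference_start)
            if a.is_reverse:
                strands.append("-")
                seqs.append(_rc(a.query_sequence))
            else:
                strands.append("+")
                seqs.append(a.query_sequence)
    return ReadSet(
        reference=reference,
        ids=ids,
        starts=np.array(starts),
        strands=np.array(strands),
        seqs=seqs,
        min_len=min_len,
    )


def read_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path!r}")
    return str(records[0].seq)


def write_fasta(seq: str, path: str | Path, name: str = "ref") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
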