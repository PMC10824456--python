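"""Readers and writers for the on-disk formats.

Plain-text formats throughout: FASTA for sequences, TSV for the ontology
edge list (child, parent, namespace; roots carry an empty parent), TSV for
annotations and predictions, JSON for reports and manifests, and an NPZ
archive for model weights.  All writers are deterministic: stable row
ordering and fixed decimal formatting (9 significant digits for scores),
with an optional hex-float mode for bit-exact cross-environment diffs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metrics import Ontology

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_ontology",
    "write_ontology",
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
    "write_report",
    "read_report",
    "save_weights",
    "load_weights",
    "write_manifest",
]


def read_fasta(path) -> list:
    """Read protein records; duplicate or empty ids and empty sequences are
    rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    seen = set()
    for rec in records:
        if not rec.id:
            raise ValueError(f"{path}: record with empty id")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
    return records


def write_fasta(records: Iterable, path) -> None:
    recs = [
        r if isinstance(r, SeqRecord) else SeqRecord(Seq(str(r[1])), id=str(r[0]), description="")
        for r in records
    ]
    for r in recs:
        r.description = ""
    SeqIO.write(recs, str(path), "fasta")


def write_ontology(ontology: Ontology, path) -> None:
    """Edge-list TSV: child, parent, namespace; one row per edge plus one
    parentless row per root."""
    with open(path, "w") as fh:
        fh.write("child\tparent\tnamespace\n")
        for root in ontology.roots:
            fh.write(f"{root}\t\t{root}\n")
        for child, parent in sorted(ontology.graph.edges):
            fh.write(f"{child}\t{parent}\t{ontology.namespace_of(child)}\n")


def read_ontology(path) -> Ontology:
    edges = []
    nodes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["child", "parent"]:
            raise ValueError(f"{path}: expected columns child/parent, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            child, parent = parts[0], parts[1]
            nodes.append(child)
            if parent:
                edges.append((child, parent))
    return Ontology(edges, nodes=nodes)


def read_annotations(path) -> Dict[str, set]:
    """TSV with columns protein, class -> protein id to class-id set."""
    out: Dict[str, set] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein", "class"]:
            raise ValueError(f"{path}: expected columns protein/class, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected protein<TAB>class")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_annotations(annotations: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tclass\n")
        for protein in sorted(annotations):
            for c in sorted(annotations[protein]):
                fh.write(f"{protein}\t{c}\n")


def _fmt_score(x: float, hex_floats: bool) -> str:
    return float(x).hex() if hex_floats else format(float(x), ".9g")


def write_predictions(pred, path, hex_floats: bool = False) -> None:
    """Prediction TSV (protein, class, score), sorted by (protein, class)
    for diffability.  ``hex_floats`` switches to lossless C99 hex floats."""
    rows = sorted(
        (p, c, pred.scores[i, j])
        for i, p in enumerate(pred.protein_ids)
        for j, c in enumerate(pred.class_ids)
    )
    with open(path, "w") as fh:
        fh.write("protein\tclass\tscore\n")
        for p, c, s in rows:
            fh.write(f"{p}\t{c}\t{_fmt_score(s, hex_floats)}\n")


def read_predictions(path):
    """Read a prediction TSV back as ``(scores_by_protein, class set)``;
    scores outside [0, 1] are rejected."""
    out: Dict[str, Dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein", "class", "score"]:
            raise ValueError(f"{path}: expected columns protein/class/score, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            p, c, raw = parts[0], parts[1], parts[2]
            s = float.fromhex(raw) if raw.startswith(("0x", "-0x")) else float(raw)
            if not 0.0 <= s <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: score {s} outside [0, 1] (column 'score')"
                )
            out.setdefault(p, {})[c] = s
    return out


def write_report(report, path) -> None:
    """Serialise a report (dict or DataFrame) to JSON, loss-free."""
    if hasattr(report, "to_dict"):
        payload = report.to_dict(orient="records")
    else:
        payload = report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_report(path):
    with open(path) as fh:
        return json.load(fh)


def save_weights(weights: Mapping[str, np.ndarray], path) -> None:
    """Portable compressed array archive with named arrays."""
    np.savez_compressed(str(path), **{k: np.asarray(v) for k, v in weights.items()})


def load_weights(path) -> Dict[str, np.ndarray]:
    with np.load(str(path)) as npz:
        return {k: npz[k] for k in npz.files}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: Mapping, seeds: Mapping, backend: str,
                   inputs: Optional[Mapping[str, str]] = None) -> Path:
    """Write the run manifest: config echo, seeds, backend, tool version and
    input checksums — enough to re-run the experiment."""
    from . import __version__

    manifest = {
        "tool": "fuzzyfunc",
        "version": __version__,
        "backend": backend,
        "config": dict(config),
        "seeds": dict(seeds),
        "input_checksums": {
            name: _sha256(p) for name, p in (inputs or {}).items()
        },
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
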