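"""File formats: label-pair TSV, Matrix Market, assignments, corpora, reports.

The gold file defines the document and label universes; prediction files are
resolved against the maps built from gold, and ids absent from gold are
rejected by name (the application's label vocabulary is fixed in advance).
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .components import Document, tokenize
from .ensemble import CandidateEvidence, EnsembleAssignment
from .matrices import LabelMatrix

__all__ = [
    "DataFormatError",
    "ContractError",
    "IdMaps",
    "read_label_pairs",
    "write_label_pairs",
    "write_assignment",
    "read_assignment",
    "write_report",
    "read_corpus",
    "read_mesh_terms",
    "RunConfig",
    "read_config",
]

logger = logging.getLogger(__name__)


class DataFormatError(ValueError):
    """Malformed or inconsistent input file."""


class ContractError(ValueError):
    """Inputs violate a cross-file contract (unknown ids, shape mismatch)."""


@dataclass(frozen=True)
class IdMaps:
    """Stable string-id ↔ index maps shared across files of one run."""

    doc_index: dict
    label_index: dict

    @property
    def doc_ids(self) -> list[str]:
        return [d for d, _ in sorted(self.doc_index.items(), key=lambda kv: kv[1])]

    @property
    def label_ids(self) -> list[str]:
        return [d for d, _ in sorted(self.label_index.items(), key=lambda kv: kv[1])]


def _is_matrix_market(path: Path) -> bool:
    if path.suffix == ".mtx":
        return True
    with open(path, "rb") as fh:
        return fh.read(14) == b"%%MatrixMarket"


def read_label_pairs(
    path, id_maps: IdMaps | None = None
) -> tuple[LabelMatrix, IdMaps]:
    """Read a binary assignment from TSV pairs or Matrix Market coordinates.

    TSV: two tab-separated columns (document-id, label-id) with arbitrary
    string ids. Without ``id_maps`` the file defines the universe (gold);
    with it, ids are resolved against the maps and unknown ids are rejected
    by name. Duplicate pairs collapse to one entry with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    if path.stat().st_size and _is_matrix_market(path):
        m = scipy.io.mmread(path)
        if id_maps is not None:
            n_docs, n_labels = len(id_maps.doc_index), len(id_maps.label_index)
            if m.shape != (n_docs, n_labels):
                raise ContractError(
                    f"{path}: matrix shape {m.shape} does not match the gold "
                    f"universe ({n_docs}, {n_labels})"
                )
            return LabelMatrix(m), id_maps
        maps = IdMaps(
            doc_index={str(i): i for i in range(m.shape[0])},
            label_index={str(j): j for j in range(m.shape[1])},
        )
        return LabelMatrix(m), maps

    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise DataFormatError(
                    f"{path}:{lineno}: expected two tab-separated ids, got {line!r}"
                )
            pairs.append((parts[0], parts[1]))

    if id_maps is None:
        doc_index: dict = {}
        label_index: dict = {}
        for d, l in pairs:
            doc_index.setdefault(d, len(doc_index))
            label_index.setdefault(l, len(label_index))
        id_maps = IdMaps(doc_index=doc_index, label_index=label_index)
    else:
        for d, l in pairs:
            if d not in id_maps.doc_index:
                raise ContractError(f"{path}: document id {d!r} absent from gold")
            if l not in id_maps.label_index:
                raise ContractError(f"{path}: label id {l!r} absent from gold")
    coords = {(id_maps.doc_index[d], id_maps.label_index[l]) for (d, l) in pairs}
    if len(coords) < len(pairs):
        logger.warning("%s: %d duplicate pair line(s) collapsed", path, len(pairs) - len(coords))
    matrix = LabelMatrix.from_pairs(
        coords, n_instances=len(id_maps.doc_index), n_labels=len(id_maps.label_index)
    )
    return matrix, id_maps


def write_label_pairs(matrix: LabelMatrix, path, id_maps: IdMaps | None = None) -> None:
    """Write TSV pairs (or Matrix Market when the path ends in .mtx)."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), matrix.tocsc().tocoo(), field="integer")
        return
    doc_ids = id_maps.doc_ids if id_maps else [str(i) for i in range(matrix.n_instances)]
    label_ids = id_maps.label_ids if id_maps else [str(j) for j in range(matrix.n_labels)]
    coo = matrix.tocsc().tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w", encoding="utf-8") as fh:
        for k in order:
            fh.write(f"{doc_ids[coo.row[k]]}\t{label_ids[coo.col[k]]}\n")


# ---------------------------------------------------------------------------
# assignments

_ASSIGN_HEADER = "label_id\tselected_model_id\traw_p\tadjusted_p\tmetric_delta\tn01\tn10"


def write_assignment(
    assignment: EnsembleAssignment, path, label_ids: Sequence[str] | None = None
) -> None:
    """Serialize per-label selections and the selected model's evidence.

    Floats are written with full round-trip precision; labels kept on M1
    without a test carry NA evidence fields.
    """
    label_ids = label_ids or [str(j) for j in range(assignment.n_labels)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# strategy={assignment.strategy}\tmetric={assignment.metric}\t"
                 f"alpha={assignment.alpha}\tglobal_best={assignment.global_best}\t"
                 f"models={','.join(assignment.model_ids)}\n")
        fh.write(_ASSIGN_HEADER + "\n")
        for l, model in enumerate(assignment.selected):
            ev = None
            for cand in assignment.evidence.get(l, ()):
                if cand.model_id == model and model != assignment.global_best:
                    ev = cand
                    break
            def fmt(x):
                return "NA" if x is None else repr(x)
            if ev is None:
                fh.write(f"{label_ids[l]}\t{model}\tNA\tNA\tNA\tNA\tNA\n")
            else:
                fh.write(
                    f"{label_ids[l]}\t{model}\t{fmt(ev.p_raw)}\t{fmt(ev.p_adjusted)}\t"
                    f"{fmt(ev.metric_delta)}\t{fmt(ev.n01)}\t{fmt(ev.n10)}\n"
                )


def read_assignment(path) -> EnsembleAssignment:
    """Read an assignment TSV back; round-trips the serialized fields."""
    path = Path(path)
    meta: dict[str, str] = {}
    selected: list[str] = []
    evidence: dict[int, tuple[CandidateEvidence, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# "):
            raise DataFormatError(f"{path}: missing assignment metadata header")
        for item in header[2:].split("\t"):
            k, _, v = item.partition("=")
            meta[k] = v
        columns = fh.readline().rstrip("\n")
        if columns != _ASSIGN_HEADER:
            raise DataFormatError(f"{path}: unexpected column header {columns!r}")
        for lineno, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise DataFormatError(f"{path}:{lineno}: expected 7 columns")
            _, model, p_raw, p_adj, delta, n01, n10 = parts
            l = len(selected)
            selected.append(model)
            if p_raw != "NA" or delta != "NA":
                evidence[l] = (
                    CandidateEvidence(
                        model_id=model,
                        metric_delta=float(delta) if delta != "NA" else 0.0,
                        p_raw=None if p_raw == "NA" else float(p_raw),
                        p_adjusted=None if p_adj == "NA" else float(p_adj),
                        n01=None if n01 == "NA" else int(n01),
                        n10=None if n10 == "NA" else int(n10),
                        rejected=True,
                    ),
                )
    alpha = meta.get("alpha", "None")
    return EnsembleAssignment(
        model_ids=tuple(meta["models"].split(",")),
        global_best=meta["global_best"],
        selected=tuple(selected),
        strategy=meta["strategy"],
        metric=meta["metric"],
        alpha=None if alpha == "None" else float(alpha),
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# reports


def write_report(
    assignment: EnsembleAssignment,
    metrics: Mapping[str, Mapping[str, float]],
    path_prefix,
) -> tuple[Path, Path]:
    """Write a machine-readable JSON report and a human-readable table.

    ``metrics`` maps split name → {entry name → score}, e.g.
    ``{"validation": {"M1": 0.58, "ensemble": 0.59}}``. The report includes
    the number of labels assigned to each model; the counts partition the
    label set.
    """
    prefix = Path(path_prefix)
    counts = assignment.labels_per_model()
    payload = {
        "strategy": assignment.strategy,
        "metric": assignment.metric,
        "alpha": assignment.alpha,
        "global_best": assignment.global_best,
        "n_labels": assignment.n_labels,
        "labels_per_model": counts,
        "n_switched": len(assignment.switched_labels()),
        "metrics": {split: dict(vals) for split, vals in metrics.items()},
    }
    json_path = prefix.with_suffix(".json")
    txt_path = prefix.with_suffix(".txt")
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = [
        f"strategy: {assignment.strategy} (metric {assignment.metric}, "
        f"alpha {assignment.alpha})",
        f"global best model: {assignment.global_best}",
        "",
        "labels assigned per model:",
    ]
    for m in assignment.model_ids:
        lines.append(f"  {m:20s} {counts[m]:8d}")
    lines.append(f"  {'total':20s} {assignment.n_labels:8d}")
    for split, vals in metrics.items():
        lines.append("")
        lines.append(f"{split} metrics:")
        for name, v in vals.items():
            lines.append(f"  {name:20s} {v:.5f}")
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return json_path, txt_path


# ---------------------------------------------------------------------------
# corpora


def read_corpus(path) -> list[Document]:
    """Read a text corpus: JSON-lines or tab-delimited records.

    Each record carries id, title, abstract, journal, year and a
    comma-separated (TSV) or list-valued (JSONL) label field.
    """
    path = Path(path)
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        is_json = first.lstrip().startswith("{")
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                if is_json:
                    rec = json.loads(line)
                    labels = rec.get("labels", [])
                else:
                    fields = line.split("\t")
                    if len(fields) != 6:
                        raise ValueError("expected 6 tab-separated fields")
                    rec = dict(
                        zip(["id", "title", "abstract", "journal", "year", "labels"], fields)
                    )
                    labels = [x for x in rec["labels"].split(",") if x]
                docs.append(
                    Document(
                        doc_id=str(rec["id"]),
                        title_tokens=tokenize(str(rec["title"])),
                        body_tokens=tokenize(str(rec["abstract"])),
                        journal=str(rec.get("journal", "")),
                        year=int(rec.get("year", 2000)),
                        gold_labels=frozenset(labels),
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
    return docs


def read_mesh_terms(path) -> frozenset:
    """One controlled-vocabulary term per line, tokenized to n-gram form."""
    terms = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            toks = tokenize(line.strip())
            if toks:
                terms.add(" ".join(toks))
    return frozenset(terms)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Plain-text configuration of one end-to-end run."""

    gold_path: str = ""
    pred_paths: Mapping[str, str] = field(default_factory=dict)
    test_gold_path: str = ""
    test_pred_paths: Mapping[str, str] = field(default_factory=dict)
    strategy: str = "mule"
    metric: str = "micro-f"
    alpha: float = 0.1
    confidence: float = 0.95
    cyclic: bool = False
    max_cycles: int = 10
    out_dir: str = "."
    seed: int = 0
    verbosity: str = "INFO"


def read_config(path) -> RunConfig:
    """Parse key=value configuration with [sections]; the [predictions] and
    [test-predictions] sections map model ids to file paths."""
    cp = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        cp.read_string("[run]\n" + fh.read())
    run = cp["run"]
    return RunConfig(
        gold_path=run.get("gold", ""),
        pred_paths=dict(cp["predictions"]) if cp.has_section("predictions") else {},
        test_gold_path=run.get("test_gold", ""),
        test_pred_paths=(
            dict(cp["test-predictions"]) if cp.has_section("test-predictions") else {}
        ),
        strategy=run.get("strategy", "mule"),
        metric=run.get("metric", "micro-f"),
        alpha=run.getfloat("alpha", 0.1),
        confidence=run.getfloat("confidence", 0.95),
        cyclic=run.getboolean("cyclic", False),
        max_cycles=run.getint("max_cycles", 10),
        out_dir=run.get("out_dir", "."),
        seed=run.getint("seed", 0),
        verbosity=run.get("verbosity", "INFO"),
    )
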