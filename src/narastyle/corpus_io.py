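"""Readers and writers: corpus records, feature tables, result tables.

The corpus interchange format is JSON lines — one narrative per line,
UTF-8, with an optional embedded annotation block (per-sentence tokens,
chunk spans and chunk dependency heads).  The format is parser-agnostic:
annotations may come from any morphological analyzer / dependency parser
adapter or from the synthetic generator.  Readers validate and reject
malformed records with their line number; they never silently repair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .exceptions import InvalidInputError, ValidationError
from .group_compare import ComparisonTable
from .preprocess import RawDocument, Sentence, count_chars
from .stylometry import (
    AnnotatedDocument,
    Chunk,
    ChunkedSentence,
    FeatureVector,
    Token,
)

logger = logging.getLogger("narastyle")

PathArg = Union[str, PathLike]


@dataclass(frozen=True)
class CorpusRecord:
    """One narrative as stored on disk: raw text plus optional annotations."""

    raw: RawDocument
    annotated: Optional[AnnotatedDocument] = None


def _sentence_to_json(cs: ChunkedSentence) -> dict:
    return {
        "text": cs.sentence.text,
        "is_conversational": cs.sentence.is_conversational,
        "tokens": [[t.surface, t.pos, t.chunk_index] for t in cs.tokens],
        "chunk_spans": [[c.start, c.end] for c in cs.chunks],
        "chunk_heads": [c.head for c in cs.chunks],
    }


def _sentence_from_json(obj: dict, index: int) -> ChunkedSentence:
    text = obj["text"]
    sentence = Sentence(
        index=index,
        text=text,
        char_count=count_chars(text),
        is_conversational=bool(obj["is_conversational"]),
    )
    tokens = tuple(
        Token(surface=s, pos=p, chunk_index=int(c)) for s, p, c in obj["tokens"]
    )
    chunks = tuple(
        Chunk(start=int(a), end=int(b), head=int(h))
        for (a, b), h in zip(obj["chunk_spans"], obj["chunk_heads"])
    )
    return ChunkedSentence(sentence=sentence, tokens=tokens, chunks=chunks)


def record_to_json(record: CorpusRecord) -> str:
    raw = record.raw
    obj = {
        "doc_id": raw.doc_id,
        "text": raw.text,
        "k10_items": list(raw.k10_items) if raw.k10_items is not None else None,
        "age_group": raw.age_group,
        "gender": raw.gender,
        "sentences": (
            [_sentence_to_json(cs) for cs in record.annotated.sentences]
            if record.annotated is not None
            else None
        ),
    }
    return json.dumps(obj, ensure_ascii=False, separators=(",", ":"))


def read_corpus(path: PathArg) -> list[CorpusRecord]:
    """Read a JSONL corpus; malformed records fail with their line number."""
    records: list[CorpusRecord] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                raw = RawDocument(
                    doc_id=str(obj["doc_id"]),
                    text=obj["text"],
                    age_group=obj.get("age_group"),
                    gender=obj.get("gender"),
                    k10_items=(
                        tuple(obj["k10_items"])
                        if obj.get("k10_items") is not None
                        else None
                    ),
                )
                annotated = None
                if obj.get("sentences"):
                    sentences = tuple(
                        _sentence_from_json(s, i)
                        for i, s in enumerate(obj["sentences"])
                    )
                    annotated = AnnotatedDocument(raw=raw, sentences=sentences)
            except (KeyError, TypeError, json.JSONDecodeError, ValueError) as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            if raw.doc_id in seen_ids:
                raise ValidationError(f"line {lineno}: duplicate doc_id {raw.doc_id!r}")
            seen_ids.add(raw.doc_id)
            records.append(CorpusRecord(raw=raw, annotated=annotated))
    logger.info("read %d corpus records from %s", len(records), path)
    return records


def write_corpus(records: Sequence[CorpusRecord], path: PathArg) -> None:
    """Write records as JSON lines (canonical form: round-trip stable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(record_to_json(record))
            fh.write("\n")
    logger.info("wrote %d corpus records to %s", len(records), path)


def write_features(
    features: Sequence[FeatureVector],
    doc_ids: Sequence[str],
    path: PathArg,
) -> None:
    """Per-document feature matrix as CSV (one row per narrative)."""
    if len(features) != len(doc_ids):
        raise InvalidInputError("features and doc_ids must align")
    df = pd.DataFrame([f.as_dict() for f in features])
    df.insert(0, "doc_id", list(doc_ids))
    df.to_csv(path, index=False, encoding="utf-8")
    logger.info("wrote %d feature rows to %s", len(df), path)


def write_results(table: ComparisonTable, path: PathArg) -> None:
    """Comparison table as CSV, 3-decimal display precision.

    The display file mirrors the fixed row/column layout of the printed
    report; a companion ``*_full.csv`` keeps full float precision.  Run
    metadata (seed, cutoff, test variant, emotion mode) goes into
    ``#``-prefixed header comment lines of both files.
    """
    if not table.rows:
        raise InvalidInputError("cannot write an empty comparison table")
    path = Path(path)
    df = table.to_dataframe()
    header = "".join(
        f"# {key}: {value}\n" for key, value in sorted(table.metadata.items())
    )
    for target, fmt in ((path, "%.3f"), (path.with_name(path.stem + "_full.csv"), None)):
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format=fmt)
    logger.info("wrote comparison table (%d rows) to %s", len(df), path)
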