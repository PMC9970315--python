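"""Consensus miRNA-target voting across prediction tools.

Five public target-prediction tools (DIANA, Miranda, PicTar, TargetScan,
miRDB) disagree heavily; the standard remedy is a vote: keep a
(miRNA, gene) pair only when at least ``min_tools`` distinct tools
predict it, then take the per-miRNA union of the kept targets.  Votes
count tools, not records — duplicate rows within one tool count once.
Tool-native scores are carried through but never combined.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionRecord",
    "ConsensusTargetSet",
    "load_predictions",
    "consensus_targets",
    "consensus_to_frame",
    "write_consensus",
]

_ALLOWED_COLUMNS = {"mirna", "gene", "score"}


@dataclass(frozen=True)
class PredictionRecord:
    """One tool's claim that a miRNA targets a gene."""

    tool: str
    mirna: str
    gene: str
    score: float | None = None

    def __post_init__(self):
        for attr in ("tool", "mirna", "gene"):
            if not getattr(self, attr):
                raise ValueError(f"PredictionRecord.{attr} must be non-empty")


@dataclass(frozen=True)
class ConsensusTargetSet:
    """Kept targets of one miRNA with the per-gene tool vote counts."""

    mirna: str
    targets: frozenset
    vote_count: dict = field(compare=False)
    min_tools: int = 3

    def __post_init__(self):
        for gene in self.targets:
            if self.vote_count.get(gene, 0) < self.min_tools:
                raise ValueError(
                    f"target {gene} of {self.mirna} has "
                    f"{self.vote_count.get(gene, 0)} votes < threshold "
                    f"{self.min_tools}"
                )


def _normalize(identifier: str) -> str:
    """Case-insensitive exact matching: lower-case, keep punctuation.
    No ortholog or alias mapping is attempted."""
    return str(identifier).strip().lower()


def records_from_frame(df: pd.DataFrame, tool: str) -> list:
    """Build deduplicated records from a ``mirna, gene[, score]`` frame."""
    unknown = set(df.columns) - _ALLOWED_COLUMNS
    if unknown:
        raise ValueError(
            f"unknown column(s) {sorted(unknown)} in predictions for "
            f"'{tool}' (expected mirna, gene[, score])"
        )
    for col in ("mirna", "gene"):
        if col not in df.columns:
            raise ValueError(
                f"predictions for '{tool}' lack required column '{col}'"
            )
    records, seen = [], set()
    for row in df.itertuples(index=False):
        mirna = _normalize(row.mirna)
        gene = _normalize(row.gene)
        key = (mirna, gene)
        if key in seen:
            continue
        seen.add(key)
        score = float(row.score) if "score" in df.columns and \
            pd.notna(row.score) else None
        records.append(
            PredictionRecord(tool=tool, mirna=mirna, gene=gene, score=score)
        )
    return records


def load_predictions(paths, tool_names) -> list:
    """Read one delimited prediction file per tool.

    Files are TSV or CSV (sniffed) with a header containing ``mirna`` and
    ``gene`` and optionally ``score``.  Identifiers are lower-cased so
    matching is case-insensitive; rows duplicated within a tool are
    dropped.  An unknown column rejects the file by name; an empty file
    yields no records with a warning.
    """
    paths = [Path(p) for p in paths]
    if len(paths) != len(tool_names):
        raise ValueError("need exactly one tool name per file")
    records = []
    for path, tool in zip(paths, tool_names):
        if not path.read_text().strip():
            warnings.warn(f"prediction file {path} is empty", stacklevel=2)
            continue
        try:
            df = pd.read_csv(path, sep=None, engine="python")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["mirna", "gene"])
        df.columns = [str(c).strip().lower() for c in df.columns]
        if df.empty:
            warnings.warn(f"prediction file {path} has no rows",
                          stacklevel=2)
            continue
        try:
            parsed = records_from_frame(df, tool)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
        logger.info("parsed %d prediction records from %s", len(parsed), path)
        records.extend(parsed)
    return records


def consensus_targets(records, min_tools: int = 3) -> list:
    """Per-miRNA union of targets predicted by >= ``min_tools`` tools.

    Returns one :class:`ConsensusTargetSet` per miRNA that retains at
    least one target, sorted by miRNA id (and gene within each set via
    the vote-count mapping's sorted keys).
    """
    tools_present = {r.tool for r in records}
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    if records and min_tools > len(tools_present):
        raise ValueError(
            f"min_tools={min_tools} exceeds the {len(tools_present)} "
            f"distinct tools present"
        )
    votes: dict = {}
    for r in records:
        votes.setdefault(r.mirna, {}).setdefault(r.gene, set()).add(r.tool)
    out = []
    for mirna in sorted(votes):
        counts = {g: len(t) for g, t in sorted(votes[mirna].items())}
        kept = frozenset(g for g, c in counts.items() if c >= min_tools)
        if kept:
            out.append(
                ConsensusTargetSet(
                    mirna=mirna,
                    targets=kept,
                    vote_count=counts,
                    min_tools=min_tools,
                )
            )
    return out


def consensus_to_frame(consensus) -> pd.DataFrame:
    """Flatten consensus sets to a ``mirna, gene, vote_count`` table."""
    rows = [
        (c.mirna, gene, c.vote_count[gene])
        for c in consensus
        for gene in sorted(c.targets)
    ]
    return pd.DataFrame(rows, columns=["mirna", "gene", "vote_count"])


def write_consensus(consensus, out_tsv, out_json=None, tool_names=None):
    """Write the consensus table as TSV plus an optional JSON summary."""
    df = consensus_to_frame(consensus)
    df.to_csv(out_tsv, sep="\t", index=False)
    if out_json is not None:
        summary = {
            "tools": list(tool_names) if tool_names else None,
            "min_tools": consensus[0].min_tools if consensus else None,
            "n_mirnas": int(df["mirna"].nunique()) if len(df) else 0,
            "n_targets": int(len(df)),
        }
        Path(out_json).write_text(json.dumps(summary, indent=2))
    return df
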