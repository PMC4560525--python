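"""Core domain types and tabular/FASTA I/O.

All residue coordinates are 1-based and spans are inclusive at both ends;
conversion to 0-based indexing happens only inside functions, never in the
types. Sequences are restricted to the 20 canonical one-letter amino-acid
codes — ambiguity codes (B, Z, X, ...) are rejected at parse time because the
downstream propensity scorer has no parameters for them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

VARIANT_LABELS = ("pathogenic", "neutral", "unlabeled")


class ParseError(ValueError):
    """Malformed on-disk input (bad FASTA, bad residue code, bad table)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a cross-record invariant."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A single protein chain with a canonical amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = [i for i, aa in enumerate(self.sequence) if aa not in _CANONICAL_SET]
        if bad:
            i = bad[0]
            raise ParseError(
                f"invalid residue {self.sequence[i]!r} at {self.protein_id}:{i + 1}"
            )
        if not self.sequence:
            raise ParseError(f"empty sequence for {self.protein_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValidationError(
                f"position {position} out of range for {self.protein_id} "
                f"(length {self.length})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Variant:
    """One missense substitution, keyed to a protein position (1-based)."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.wt_aa not in _CANONICAL_SET or self.mut_aa not in _CANONICAL_SET:
            raise ParseError(
                f"non-canonical residue in variant {self.key}"
            )
        if self.wt_aa == self.mut_aa:
            raise ValidationError(f"synonymous substitution {self.key}")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1 in {self.key}")
        if self.label not in VARIANT_LABELS:
            raise ValidationError(f"unknown label {self.label!r} in {self.key}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)

    def check_against(self, protein: ProteinRecord) -> None:
        """Raise unless the variant is consistent with the sequence."""
        if self.position > protein.length:
            raise ValidationError(
                f"{self.key}: position out of range (length {protein.length})"
            )
        seq_aa = protein.residue(self.position)
        if seq_aa != self.wt_aa:
            raise ValidationError(
                f"{self.key}: wt mismatch (sequence has {seq_aa})"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """A structural-domain span within one protein (inclusive bounds)."""

    protein_id: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"bad domain span {self.domain_id}: {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class StabilityRecord:
    """Free-energy change of stability upon mutation (kcal/mol).

    Positive ddG destabilizes the native state; negative stabilizes.
    """

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    ddg: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise ValidationError(f"non-finite ddG for {self.key}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)


@dataclass
class ScoreTrack:
    """Per-residue aggregation propensity on a percent scale [0, 100]."""

    protein_id: str
    scores: np.ndarray

    VALID_RANGE = (0.0, 100.0)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        _check_track(self.scores, self.VALID_RANGE, self.protein_id)

    def __len__(self) -> int:
        return len(self.scores)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        return self.protein_id == other.protein_id and np.array_equal(
            self.scores, other.scores
        )


@dataclass
class DisorderTrack:
    """Per-residue disorder propensity in [0, 1]."""

    protein_id: str
    scores: np.ndarray

    VALID_RANGE = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        _check_track(self.scores, self.VALID_RANGE, self.protein_id)

    def __len__(self) -> int:
        return len(self.scores)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        return self.protein_id == other.protein_id and np.array_equal(
            self.scores, other.scores
        )


def _check_track(scores: np.ndarray, rng: tuple[float, float], pid: str) -> None:
    if scores.ndim != 1 or len(scores) == 0:
        raise ValidationError(f"track for {pid} must be a non-empty vector")
    if not np.all(np.isfinite(scores)):
        raise ValidationError(f"non-finite score in track for {pid}")
    lo, hi = rng
    if scores.min() < lo or scores.max() > hi:
        raise ValidationError(
            f"score out of range [{lo}, {hi}] in track for {pid}"
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences; ids are headers up to the first whitespace."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA entry with empty header")
        seq = str(rec.seq).upper()
        try:
            records.append(ProteinRecord(rec.id, seq))
        except ParseError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file, header required") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_variant_table(
    path: str | Path,
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> list[Variant]:
    """Read a TSV of variants; validates against sequences when given.

    Required columns: protein_id, position, wt_aa, mut_aa. A ``label``
    column is optional (defaults to ``unlabeled``). All validation failures
    are collected and reported together rather than stopping at the first.
    """
    df = _read_tsv(path, ["protein_id", "position", "wt_aa", "mut_aa"])
    variants: list[Variant] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        label = row.get("label", "unlabeled")
        if pd.isna(label):
            label = "unlabeled"
        try:
            v = Variant(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                wt_aa=row["wt_aa"],
                mut_aa=row["mut_aa"],
                label=str(label),
            )
            if proteins is not None:
                if v.protein_id not in proteins:
                    raise ValidationError(f"unknown protein {v.protein_id}")
                v.check_against(proteins[v.protein_id])
            variants.append(v)
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx + 2}: {exc}")
    if errors:
        raise ValidationError(f"{path}: invalid variant rows:\n" + "\n".join(errors))
    return variants


def read_track(path: str | Path, kind: str) -> list[ScoreTrack | DisorderTrack]:
    """Read per-residue tracks (columns protein_id, position, score).

    ``kind`` is "aggregation" (scores validated to [0, 100]) or "disorder"
    ([0, 1]). Positions of each protein must be contiguous 1..L.
    """
    if kind not in ("aggregation", "disorder"):
        raise ValueError(f"unknown track kind {kind!r}")
    cls = ScoreTrack if kind == "aggregation" else DisorderTrack
    df = _read_tsv(path, ["protein_id", "position", "score"])
    tracks: list[ScoreTrack | DisorderTrack] = []
    for pid, grp in df.groupby("protein_id", sort=True):
        pos = grp["position"].astype(int).to_numpy()
        scores = grp["score"].astype(float).to_numpy()
        order = np.argsort(pos)
        pos, scores = pos[order], scores[order]
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            raise ValidationError(
                f"{path}: non-contiguous track for {pid} "
                f"(positions must be exactly 1..{len(pos)})"
            )
        tracks.append(cls(str(pid), scores))
    return tracks


def read_domain_table(
    path: str | Path,
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> list[DomainAnnotation]:
    """Read domain spans; overlapping domains within a protein are rejected."""
    df = _read_tsv(path, ["protein_id", "domain_id", "start", "end"])
    domains = [
        DomainAnnotation(
            protein_id=row["protein_id"],
            domain_id=row["domain_id"],
            start=int(row["start"]),
            end=int(row["end"]),
        )
        for _, row in df.iterrows()
    ]
    check_domains(domains, proteins)
    return domains


def check_domains(
    domains: Iterable[DomainAnnotation],
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> None:
    """Enforce the no-overlap invariant (and bounds when sequences given)."""
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_protein.setdefault(d.protein_id, []).append(d)
    for pid, doms in by_protein.items():
        if proteins is not None:
            if pid not in proteins:
                raise ValidationError(f"domain references unknown protein {pid}")
            L = proteins[pid].length
            for d in doms:
                if d.end > L:
                    raise ValidationError(
                        f"domain {d.domain_id} exceeds {pid} length {L}"
                    )
        doms = sorted(doms, key=lambda d: d.start)
        for a, b in zip(doms, doms[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping domains {a.domain_id} and {b.domain_id} on {pid}"
                )


def read_ddg_table(path: str | Path) -> list[StabilityRecord]:
    """Read per-variant ddG values (kcal/mol, positive = destabilizing)."""
    df = _read_tsv(path, ["protein_id", "position", "wt_aa", "mut_aa", "ddg"])
    return [
        StabilityRecord(
            protein_id=row["protein_id"],
            position=int(row["position"]),
            wt_aa=row["wt_aa"],
            mut_aa=row["mut_aa"],
            ddg=float(row["ddg"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, p.length, 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_variant_table(variants: Iterable[Variant], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": v.protein_id,
                "position": v.position,
                "wt_aa": v.wt_aa,
                "mut_aa": v.mut_aa,
                "label": v.label,
            }
            for v in variants
        ],
        columns=["protein_id", "position", "wt_aa", "mut_aa", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_track(
    tracks: Iterable[ScoreTrack | DisorderTrack], path: str | Path
) -> None:
    rows = []
    for t in tracks:
        for i, s in enumerate(t.scores, start=1):
            rows.append({"protein_id": t.protein_id, "position": i, "score": s})
    pd.DataFrame(rows, columns=["protein_id", "position", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_domain_table(
    domains: Iterable[DomainAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": d.protein_id,
                "domain_id": d.domain_id,
                "start": d.start,
                "end": d.end,
            }
            for d in domains
        ],
        columns=["protein_id", "domain_id", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_ddg_table(records: Iterable[StabilityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "position": r.position,
                "wt_aa": r.wt_aa,
                "mut_aa": r.mut_aa,
                "ddg": r.ddg,
            }
            for r in records
        ],
        columns=["protein_id", "position", "wt_aa", "mut_aa", "ddg"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


#: Stable column order of the per-variant classification table.
CLASSIFICATION_COLUMNS = [
    "protein_id",
    "position",
    "wt_aa",
    "mut_aa",
    "label",
    "intrinsic_category",
    "intrinsic_direction",
    "delta_score",
    "ddg",
    "stability_class",
    "disordered",
    "domain_id",
    "domain_strongest_apr",
    "aggregation_increasing",
]


def write_classification_table(classifications, path: str | Path) -> None:
    """Write per-variant verdicts, sorted by (protein_id, position, mut_aa).

    Missing values (no ddG, no domain, no disorder track) are written as
    ``NA``; the output is byte-deterministic for a given input set.
    """
    rows = []
    for c in classifications:
        rows.append(c.as_row())
    rows.sort(key=lambda r: (r["protein_id"], r["position"], r["mut_aa"]))
    df = pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_run_summary(summary: Mapping, path: str | Path) -> None:
    """Write the JSON run summary (counts, thresholds, seed)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
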