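"""Bidirectional best-hit (BBH) orthology over similarity hit tables.

Orthologs between the reference genome and a target genome are called by
the classic reciprocal-best-hit criterion: gene ``r`` in the reference and
gene ``t`` in the target are orthologs when ``t`` is the best hit of ``r``
in the forward search, ``r`` is the best hit of ``t`` in the reverse
search, and both best hits clear the acceptance thresholds (e-value below
1e-6, percent identity above 30, and alignment length covering more than
60% of each of the two proteins).

Hit tables are consumed in BLAST tabular form (``-outfmt 6``, 12 columns);
protein lengths, which outfmt 6 does not carry, come from a companion
two-column length table per genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple


class HitTableError(ValueError):
    pass


class Hit(NamedTuple):
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    query_length: int
    subject_length: int


@dataclass(frozen=True)
class Thresholds:
    """Acceptance thresholds for a candidate ortholog hit.

    All three comparisons are strict; coverage is enforced against both
    the query and the subject protein lengths.
    """

    evalue_max: float = 1e-6
    identity_min: float = 30.0
    coverage_min: float = 0.60


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one reference-gene -> target-gene ortholog pairing."""

    genome_id: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        refs = [r for r, _ in self.pairs]
        tgts = [t for _, t in self.pairs]
        if len(set(refs)) != len(refs) or len(set(tgts)) != len(tgts):
            raise ValueError("ortholog map is not one-to-one")

    @property
    def by_ref(self) -> dict[str, str]:
        return {r: t for r, t in self.pairs}

    @property
    def by_target(self) -> dict[str, str]:
        return {t: r for r, t in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, ref_gene_id: str) -> bool:
        return any(r == ref_gene_id for r, _ in self.pairs)


def read_length_table(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, length) TSV of protein lengths."""
    path = Path(path)
    out: dict[str, int] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HitTableError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            out[fields[0].strip()] = int(fields[1])
    return out


def read_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
) -> list[Hit]:
    """Read a 12-column BLAST tabular (outfmt 6) hit table.

    Column order: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Hits are returned in file order.  A
    query or subject id missing from the length tables is an error naming
    the id.
    """
    path = Path(path)
    hits: list[Hit] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise HitTableError(
                    f"{path}:{lineno}: expected 12 columns, got {len(f)}"
                )
            qid, sid = f[0].strip(), f[1].strip()
            if qid not in query_lengths:
                raise HitTableError(
                    f"{path}:{lineno}: no length entry for query {qid!r}"
                )
            if sid not in subject_lengths:
                raise HitTableError(
                    f"{path}:{lineno}: no length entry for subject {sid!r}"
                )
            hits.append(
                Hit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=float(f[2]),
                    alignment_length=int(f[3]),
                    mismatches=int(f[4]),
                    gap_opens=int(f[5]),
                    qstart=int(f[6]),
                    qend=int(f[7]),
                    sstart=int(f[8]),
                    send=int(f[9]),
                    evalue=float(f[10]),
                    bitscore=float(f[11]),
                    query_length=query_lengths[qid],
                    subject_length=subject_lengths[sid],
                )
            )
    return hits


def write_hit_table(hits: Iterable[Hit], path: str | Path) -> Path:
    """Write hits back out in 12-column outfmt-6 order (lengths are not
    part of the format and go to the companion length tables)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.1f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )
    return path


def passes_thresholds(hit: Hit, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """True iff the hit clears all three acceptance thresholds (strictly)."""
    cov = thresholds.coverage_min
    return (
        hit.evalue < thresholds.evalue_max
        and hit.percent_identity > thresholds.identity_min
        and hit.alignment_length > cov * hit.query_length
        and hit.alignment_length > cov * hit.subject_length
    )


def best_hit_per_query(hits: Iterable[Hit]) -> dict[str, Hit]:
    """Best hit per query: lowest e-value, ties broken by highest
    bitscore, then lexicographically smallest subject id."""
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


def bidirectional_best_hits(
    forward_hits: Iterable[Hit],
    reverse_hits: Iterable[Hit],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    genome_id: str = "",
) -> OrthologMap:
    """Call orthologs by reciprocal best hit.

    ``forward_hits`` are reference->target searches, ``reverse_hits``
    target->reference.  A pair (r, t) is accepted iff t is r's forward
    best hit, r is t's reverse best hit, and both best hits pass the
    thresholds.  The result is one-to-one by construction.
    """
    fwd_best = best_hit_per_query(forward_hits)
    rev_best = best_hit_per_query(reverse_hits)
    pairs: set[tuple[str, str]] = set()
    for r, fh in fwd_best.items():
        t = fh.subject_id
        rh = rev_best.get(t)
        if rh is None or rh.subject_id != r:
            continue
        if passes_thresholds(fh, thresholds) and passes_thresholds(rh, thresholds):
            pairs.add((r, t))
    return OrthologMap(genome_id=genome_id, pairs=frozenset(pairs))
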