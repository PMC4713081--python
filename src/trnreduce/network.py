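"""Core domain types for transcriptional regulatory networks (TRNs).

A TRN is a directed, typed graph: regulator nodes (transcription factors
and sigma factors) point at the genes whose transcription they control.
Nodes carry a kind (``TF``, ``SIGMA`` or ``TG``) and edges carry the sign
of regulation (activation, repression, dual, or unknown).  The module also
defines the per-TF annotation record (net regulatory type, NAP and
global-regulator flags) and the per-genome metadata record, together with
readers and writers for the plain TSV dialects the rest of the pipeline
consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class NodeKind(str, enum.Enum):
    TF = "TF"
    SIGMA = "SIGMA"
    TG = "TG"


class Effect(str, enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    DUAL = "dual"
    UNKNOWN = "unknown"


class RegType(str, enum.Enum):
    """Net effective regulation exerted by a TF over its target genes."""

    ACTIVATOR = "activator"
    REPRESSOR = "repressor"
    DUAL = "dual"
    UNCLASSIFIED = "unclassified"


#: The three classified regulator types, in canonical reporting order.
CLASSIFIED_TYPES = (RegType.ACTIVATOR, RegType.REPRESSOR, RegType.DUAL)


class NetworkFormatError(ValueError):
    """Raised when a network TSV is malformed or internally inconsistent."""


@dataclass(frozen=True, slots=True)
class Edge:
    regulator: str
    target: str
    effect: Effect = Effect.UNKNOWN


@dataclass(frozen=True, slots=True)
class TFAnnotation:
    tf_id: str
    reg_type: RegType
    is_nap: bool = False
    is_global: bool = False


@dataclass(frozen=True, slots=True)
class GenomeRecord:
    genome_id: str
    size_bp: int
    category: str = "free_living"

    CATEGORIES = ("free_living", "host_restricted", "obligate", "tiny", "reference")

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError(f"genome {self.genome_id}: size_bp must be positive")
        if self.category not in self.CATEGORIES:
            raise ValueError(
                f"genome {self.genome_id}: unknown category {self.category!r}"
            )


class RegulatoryNetwork:
    """A directed, typed transcriptional regulatory network.

    The network is a set, not a multigraph: duplicate edges collapse.
    Node kinds partition the node set into transcription factors (N_TF),
    sigma factors (N_SF) and non-regulatory target genes (N_G).
    """

    def __init__(
        self,
        nodes: Mapping[str, NodeKind],
        edges: Iterable[Edge],
        name: str = "",
    ) -> None:
        self.name = name
        self.nodes: dict[str, NodeKind] = dict(nodes)
        self.edges: set[Edge] = set(edges)
        for e in self.edges:
            for endpoint in (e.regulator, e.target):
                if endpoint not in self.nodes:
                    raise NetworkFormatError(
                        f"edge {e.regulator}->{e.target}: node {endpoint!r} undeclared"
                    )
            if self.nodes[e.regulator] is NodeKind.TG:
                raise NetworkFormatError(
                    f"edge {e.regulator}->{e.target}: regulator has kind TG"
                )
        # adjacency caches
        self._targets: dict[str, set[str]] = {}
        self._regulators: dict[str, set[str]] = {}
        for e in self.edges:
            self._targets.setdefault(e.regulator, set()).add(e.target)
            self._regulators.setdefault(e.target, set()).add(e.regulator)

    # -- queries ---------------------------------------------------------
    def kind(self, node_id: str) -> NodeKind:
        return self.nodes[node_id]

    def ids_of_kind(self, kind: NodeKind) -> set[str]:
        return {n for n, k in self.nodes.items() if k is kind}

    @property
    def n_tf(self) -> int:
        return sum(1 for k in self.nodes.values() if k is NodeKind.TF)

    @property
    def n_sf(self) -> int:
        return sum(1 for k in self.nodes.values() if k is NodeKind.SIGMA)

    @property
    def n_g(self) -> int:
        return sum(1 for k in self.nodes.values() if k is NodeKind.TG)

    def summary(self) -> tuple[int, int, int, int]:
        """Return ``(N_TF, N_SF, N_G, n_edges)``."""
        return (self.n_tf, self.n_sf, self.n_g, len(self.edges))

    def targets_of(self, regulator_id: str) -> set[str]:
        return self._targets.get(regulator_id, set())

    def regulators_of(self, target_id: str) -> set[str]:
        return self._regulators.get(target_id, set())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n_tf, n_sf, n_g, m = self.summary()
        return (
            f"RegulatoryNetwork({self.name!r}, N_TF={n_tf}, N_SF={n_sf}, "
            f"N_G={n_g}, edges={m})"
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_NETWORK_HEADER = ["regulator_id", "target_id", "effect", "regulator_kind"]


def read_network(path: str | Path, name: str | None = None) -> RegulatoryNetwork:
    """Read a network edge-list TSV.

    Columns: regulator_id, target_id, effect, regulator_kind.  Node kinds
    are inferred: a node that ever appears as a regulator keeps the kind
    declared there (TF or SIGMA); ids appearing only as targets become TG.
    Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    kinds: dict[str, NodeKind] = {}
    edges: list[Edge] = []
    with path.open("r", encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != _NETWORK_HEADER:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: expected header "
                        f"{_NETWORK_HEADER!r}, got {fields!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            reg, tgt, effect_s, kind_s = (f.strip() for f in fields)
            try:
                effect = Effect(effect_s)
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown effect {effect_s!r}"
                ) from None
            try:
                kind = NodeKind(kind_s)
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown regulator kind {kind_s!r}"
                ) from None
            if kind is NodeKind.TG:
                raise NetworkFormatError(
                    f"{path}:{lineno}: regulator kind must be TF or SIGMA"
                )
            prev = kinds.get(reg)
            if prev is not None and prev is not NodeKind.TG and prev is not kind:
                raise NetworkFormatError(
                    f"{path}:{lineno}: node {reg!r} declared both "
                    f"{prev.value} and {kind.value}"
                )
            kinds[reg] = kind
            kinds.setdefault(tgt, NodeKind.TG)
            edges.append(Edge(reg, tgt, effect))
        if not header_seen:
            raise NetworkFormatError(f"{path}: empty file (missing header)")
    # a target later seen as regulator gets the regulator kind
    return RegulatoryNetwork(kinds, edges, name=name or path.stem)


def write_network(net: RegulatoryNetwork, path: str | Path) -> Path:
    """Write a network in the 4-column edge-list dialect read by
    :func:`read_network`.  Isolated nodes are not representable in an edge
    list and are dropped with that caveat."""
    path = Path(path)
    rows = sorted(
        (e.regulator, e.target, e.effect.value, net.kind(e.regulator).value)
        for e in net.edges
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_NETWORK_HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


def read_tf_annotations(path: str | Path) -> dict[str, TFAnnotation]:
    """Read the TF annotation TSV: tf_id, reg_type, is_nap(0/1), is_global(0/1)."""
    path = Path(path)
    out: dict[str, TFAnnotation] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if fields[0] == "tf_id":
                continue
            if len(fields) != 4:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            tf_id, reg_type_s, nap_s, glob_s = fields
            try:
                reg_type = RegType(reg_type_s)
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown reg_type {reg_type_s!r}"
                ) from None
            out[tf_id] = TFAnnotation(
                tf_id, reg_type, is_nap=nap_s == "1", is_global=glob_s == "1"
            )
    return out


def write_tf_annotations(
    annotations: Mapping[str, TFAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("tf_id\treg_type\tis_nap\tis_global\n")
        for tf_id in sorted(annotations):
            a = annotations[tf_id]
            fh.write(
                f"{a.tf_id}\t{a.reg_type.value}\t{int(a.is_nap)}\t{int(a.is_global)}\n"
            )
    return path


def read_genome_table(path: str | Path) -> dict[str, GenomeRecord]:
    """Read genome metadata TSV: genome_id, size_bp, category."""
    path = Path(path)
    out: dict[str, GenomeRecord] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if fields[0] == "genome_id":
                continue
            if len(fields) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            gid, size_s, cat = fields
            try:
                size = int(size_s)
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: size_bp not an integer: {size_s!r}"
                ) from None
            out[gid] = GenomeRecord(gid, size, cat)
    return out


def write_genome_table(
    records: Iterable[GenomeRecord] | Mapping[str, GenomeRecord], path: str | Path
) -> Path:
    if isinstance(records, Mapping):
        records = records.values()
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("genome_id\tsize_bp\tcategory\n")
        for r in sorted(records, key=lambda r: r.genome_id):
            fh.write(f"{r.genome_id}\t{r.size_bp}\t{r.category}\n")
    return path
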