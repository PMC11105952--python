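"""Gene-set collections: KEGG-pathway-, KEGG-disease- and GO-style sets.

A collection holds named gene sets whose members all live in one declared
identifier namespace.  Human-annotated collections can be projected into
zebrafish gene space through an orthology table, and a projected collection
can be merged with a zebrafish-native one — either keeping everything, or
keeping only the human sets that have *no* zebrafish counterpart (the
"novel-only" mode, with zebrafish annotations as the ground truth).

Counterpart identity across organisms follows KEGG map numbering:
``dre04010`` and ``hsa04010`` are the same pathway.  KEGG disease entries
(``H…``) exist only for human and therefore never have a counterpart.
"""

from __future__ import annotations

import difflib
import enum
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .idmap import (
    ConversionResult,
    FormatError,
    MappingTable,
    Namespace,
    OrthologyTable,
    convert_ids,
    to_zebrafish,
)

__all__ = [
    "SourceDB",
    "AnnotationOrganism",
    "MergeMode",
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "genes_in_set",
    "orthologize_collection",
    "counterpart_key",
    "merge_collections",
]


class SourceDB(str, enum.Enum):
    KEGG_PATHWAY = "kegg_pathway"
    KEGG_DISEASE = "kegg_disease"
    GO_BP = "go_bp"
    GO_MF = "go_mf"
    GO_CC = "go_cc"


class AnnotationOrganism(str, enum.Enum):
    ZEBRAFISH = "zebrafish"
    HUMAN = "human"
    HUMAN_VIA_ORTHOLOGY = "human_via_orthology"


class MergeMode(str, enum.Enum):
    ALL = "all"
    NOVEL_ONLY = "novel_only"


_KEGG_ID = re.compile(r"([a-z]{2,4})(\d{5})")
_KEGG_DISEASE_ID = re.compile(r"H\d{5}")
_GO_ID = re.compile(r"GO:\d{7}", re.IGNORECASE)


def _infer_source_db(set_id: str) -> SourceDB:
    if _GO_ID.fullmatch(set_id):
        return SourceDB.GO_BP
    if _KEGG_DISEASE_ID.fullmatch(set_id):
        return SourceDB.KEGG_DISEASE
    return SourceDB.KEGG_PATHWAY


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with provenance."""

    set_id: str
    name: str
    members: frozenset[str]
    source_db: SourceDB = SourceDB.KEGG_PATHWAY
    annotation_organism: AnnotationOrganism = AnnotationOrganism.ZEBRAFISH

    def __post_init__(self):
        if not self.set_id.strip():
            raise ValueError("set_id must be non-empty")
        if len(self.members) < 1:
            raise ValueError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Gene sets sharing one identifier namespace and one member organism."""

    sets: list[GeneSet]
    namespace: Namespace = Namespace.SYMBOL
    organism: AnnotationOrganism = AnnotationOrganism.ZEBRAFISH
    dropped: tuple[str, ...] = ()  # set ids removed during orthology projection

    def __post_init__(self):
        self.namespace = Namespace.parse(self.namespace)
        keys = [(s.set_id, s.annotation_organism) for s in self.sets]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (set_id, annotation_organism) in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        near = difflib.get_close_matches(set_id, self.ids, n=3)
        hint = f"; nearest ids: {', '.join(near)}" if near else ""
        raise KeyError(f"unknown set id {set_id!r}{hint}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``

    Collection metadata may precede the sets in ``#key=value`` header lines
    (keys: ``namespace``, ``organism``, ``source_db``); duplicate member
    genes within a line are collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    namespace = Namespace.SYMBOL
    organism = AnnotationOrganism.ZEBRAFISH
    forced_db: SourceDB | None = None
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key, val = key.strip().lower(), val.strip()
                if key == "namespace":
                    namespace = Namespace.parse(val)
                elif key == "organism":
                    organism = AnnotationOrganism(val.lower())
                elif key == "source_db":
                    forced_db = SourceDB(val.lower())
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs id, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            set_id, name = fields[0].strip(), fields[1].strip()
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(
                GeneSet(
                    set_id=set_id,
                    name=name,
                    members=members,
                    source_db=forced_db or _infer_source_db(set_id),
                    annotation_organism=organism,
                )
            )
    return GeneSetCollection(sets, namespace=namespace, organism=organism)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Inverse of :func:`read_gmt`; members emitted sorted for byte-stable
    output.  An empty collection writes an empty, header-free file."""
    with open(path, "w") as fh:
        if not collection.sets:
            return
        fh.write(f"#namespace={collection.namespace.value}\n")
        fh.write(f"#organism={collection.organism.value}\n")
        for s in collection.sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.set_id}\t{s.name}\t{members}\n")


def genes_in_set(
    collection: GeneSetCollection,
    set_id: str,
    target_ns: str | Namespace,
    mapping: MappingTable,
) -> ConversionResult:
    """Member genes of one set, converted into ``target_ns``.

    Returns the full conversion result so unmapped members are reported
    alongside the converted identifiers.
    """
    geneset = collection.get(set_id)
    return convert_ids(
        sorted(geneset.members), collection.namespace, target_ns, mapping
    )


def orthologize_collection(
    human_collection: GeneSetCollection,
    ortho: OrthologyTable,
    min_size: int = 5,
) -> GeneSetCollection:
    """Project a human-annotated collection into zebrafish gene space.

    Each set's members are replaced by the union of all their zebrafish
    orthologs (many-to-many expansion).  Sets retaining fewer than
    ``min_size`` zebrafish genes are dropped and listed in the returned
    collection's ``dropped`` attribute — tiny projected sets make both
    enrichment tests degenerate.
    """
    if human_collection.organism == AnnotationOrganism.ZEBRAFISH:
        raise ValueError("collection to orthologize must carry human annotations")
    projected: list[GeneSet] = []
    dropped: list[str] = []
    for s in human_collection:
        result = to_zebrafish(sorted(s.members), ortho)
        members = frozenset(result.targets)
        if len(members) < min_size:
            dropped.append(s.set_id)
            continue
        projected.append(
            replace(
                s,
                members=members,
                annotation_organism=AnnotationOrganism.HUMAN_VIA_ORTHOLOGY,
            )
        )
    return GeneSetCollection(
        projected,
        namespace=ortho.zfish_ns,
        organism=AnnotationOrganism.HUMAN_VIA_ORTHOLOGY,
        dropped=tuple(dropped),
    )


def counterpart_key(set_id: str) -> str:
    """Organism-independent identity key for a set id.

    KEGG pathway ids drop their organism prefix (``dre04010`` and
    ``hsa04010`` both key to ``04010``); GO ids are organism-agnostic and
    pass through unchanged, as do KEGG disease ids (human-only, so they can
    never collide with a zebrafish set).
    """
    set_id = set_id.strip()
    if _GO_ID.fullmatch(set_id) or _KEGG_DISEASE_ID.fullmatch(set_id):
        return set_id
    m = _KEGG_ID.fullmatch(set_id)
    if m:
        return m.group(2)
    raise ValueError(f"cannot derive a counterpart key from id {set_id!r}")


def merge_collections(
    zfish: GeneSetCollection,
    human_ortho: GeneSetCollection,
    mode: str | MergeMode = MergeMode.NOVEL_ONLY,
) -> GeneSetCollection:
    """Combine zebrafish-native and orthology-projected human collections.

    ``ALL`` keeps both versions of every set (disambiguated by annotation
    organism).  ``NOVEL_ONLY`` treats zebrafish annotation as ground truth:
    all zebrafish sets are kept, and a human set enters only when its
    counterpart key matches no zebrafish set — selectively incorporating
    human annotations that lack zebrafish counterparts.
    """
    mode = MergeMode(mode) if not isinstance(mode, MergeMode) else mode
    if human_ortho.sets and zfish.namespace != human_ortho.namespace:
        raise ValueError(
            f"namespace mismatch: {zfish.namespace.value} vs {human_ortho.namespace.value}"
        )
    if mode == MergeMode.ALL:
        merged = list(zfish.sets) + list(human_ortho.sets)
    else:
        zfish_keys = {counterpart_key(s.set_id) for s in zfish.sets}
        merged = list(zfish.sets) + [
            s for s in human_ortho.sets if counterpart_key(s.set_id) not in zfish_keys
        ]
    return GeneSetCollection(
        merged, namespace=zfish.namespace, organism=zfish.organism
    )
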