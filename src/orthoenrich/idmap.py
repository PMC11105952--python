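"""Gene identifier conversion and zebrafish<->human orthology mapping.

Supports the four identifier namespaces commonly used for zebrafish genes:
NCBI (Entrez) gene IDs, Ensembl gene IDs, ZFIN IDs, and official gene
symbols.  Orthology between zebrafish and human is many-to-many — the
teleost whole-genome duplication means one human gene frequently has two
zebrafish co-orthologs — so conversions across the taxonomy expand to *all*
orthologs rather than picking one.

Mapping and orthology tables are loaded from local TSV snapshots; nothing
is fetched from the network.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Namespace",
    "FormatError",
    "MappingTable",
    "OrthologyTable",
    "ConversionResult",
    "LoadReport",
    "load_mapping_table",
    "load_orthology",
    "write_orthology",
    "convert_ids",
    "to_human",
    "to_zebrafish",
]


class FormatError(ValueError):
    """A file's structure does not match the expected layout."""


class Namespace(str, enum.Enum):
    """Supported gene-identifier namespaces."""

    NCBI = "ncbi"
    ENSEMBL = "ensembl"
    ZFIN = "zfin"
    SYMBOL = "symbol"

    @classmethod
    def parse(cls, value: "str | Namespace") -> "Namespace":
        if isinstance(value, Namespace):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            valid = ", ".join(ns.value for ns in cls)
            raise ValueError(
                f"unknown namespace {value!r}; valid options are: {valid}"
            ) from None


@dataclass(frozen=True)
class LoadReport:
    """Row accounting from loading a mapping table."""

    n_rows: int
    n_dropped_empty: int
    n_dropped_duplicate: int


@dataclass
class ConversionResult:
    """Outcome of an identifier conversion.

    Every distinct input appears in exactly one of ``mapped`` (possibly with
    several target pairs, for one-to-many relations) or ``unmapped``.
    """

    mapped: list[tuple[str, str]]
    unmapped: list[str]
    one_to_many_count: int
    keep_unmapped: bool = True

    @property
    def mapped_inputs(self) -> list[str]:
        seen: dict[str, None] = {}
        for src, _ in self.mapped:
            seen.setdefault(src)
        return list(seen)

    @property
    def targets(self) -> list[str]:
        """Distinct output identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for _, dst in self.mapped:
            seen.setdefault(dst)
        return list(seen)

    @property
    def n_inputs(self) -> int:
        return len(self.mapped_inputs) + len(self.unmapped)

    @property
    def mapped_fraction(self) -> float:
        n = self.n_inputs
        return len(self.mapped_inputs) / n if n else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [(src, dst) for src, dst in self.mapped]
        if self.keep_unmapped:
            rows += [(src, "") for src in self.unmapped]
        return pd.DataFrame(rows, columns=["input_id", "output_id"])


def _clean_ids(ids: Iterable[str]) -> list[str]:
    """Trim, drop empties, and deduplicate preserving first-appearance order."""
    out: dict[str, None] = {}
    for raw in ids:
        value = str(raw).strip()
        if value:
            out.setdefault(value)
    return list(out)


class MappingTable:
    """Multi-namespace gene-identifier correspondence table.

    Each row relates identifiers for one gene across any subset of the four
    namespaces; an empty cell means the identifier is absent for that row.
    """

    def __init__(self, frame: pd.DataFrame, report: LoadReport | None = None):
        recognized = [ns.value for ns in Namespace if ns.value in frame.columns]
        if not recognized:
            raise FormatError(
                "mapping table has no recognized namespace columns; expected a "
                "header with at least one of: ncbi, ensembl, zfin, symbol"
            )
        frame = frame[recognized].astype(str)
        for col in recognized:
            frame[col] = frame[col].str.strip()
        nonempty = (frame != "").any(axis=1)
        n_empty = int((~nonempty).sum())
        frame = frame[nonempty]
        n_before = len(frame)
        frame = frame.drop_duplicates()
        n_dup = n_before - len(frame)
        self.frame = frame.reset_index(drop=True)
        self.report = report or LoadReport(len(self.frame), n_empty, n_dup)

    @property
    def namespaces(self) -> list[Namespace]:
        return [Namespace(c) for c in self.frame.columns]

    def __len__(self) -> int:
        return len(self.frame)

    def multimap(
        self, from_ns: Namespace, to_ns: Namespace, fold_case: bool = False
    ) -> dict[str, list[str]]:
        """source value -> ordered list of distinct target values."""
        for ns in (from_ns, to_ns):
            if ns.value not in self.frame.columns:
                raise ValueError(f"namespace {ns.value!r} not present in mapping table")
        out: dict[str, list[str]] = {}
        sub = self.frame[[from_ns.value, to_ns.value]]
        for src, dst in sub.itertuples(index=False):
            if not src or not dst:
                continue
            key = src.lower() if fold_case else src
            bucket = out.setdefault(key, [])
            if dst not in bucket:
                bucket.append(dst)
        return out

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def load_mapping_table(path: str | Path) -> MappingTable:
    """Read a TSV mapping table whose header names the namespaces present.

    Rows with no populated field are dropped, duplicated rows collapsed; both
    counts are recorded in the table's :class:`LoadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return MappingTable(frame)


class OrthologyTable:
    """Unique zebrafish<->human gene pairs; many-to-many in both directions."""

    def __init__(
        self,
        frame: pd.DataFrame,
        zfish_ns: Namespace = Namespace.SYMBOL,
        human_ns: Namespace = Namespace.SYMBOL,
    ):
        if not {"zfish_id", "human_id"}.issubset(frame.columns):
            raise FormatError("orthology table requires columns zfish_id and human_id")
        frame = frame[["zfish_id", "human_id"]].astype(str)
        for col in frame.columns:
            frame[col] = frame[col].str.strip()
        frame = frame[(frame["zfish_id"] != "") & (frame["human_id"] != "")]
        self.frame = frame.drop_duplicates().reset_index(drop=True)
        self.zfish_ns = Namespace.parse(zfish_ns)
        self.human_ns = Namespace.parse(human_ns)

    def __len__(self) -> int:
        return len(self.frame)

    def multimap(self, direction: str) -> dict[str, list[str]]:
        if direction == "to_human":
            src_col, dst_col = "zfish_id", "human_id"
        elif direction == "to_zebrafish":
            src_col, dst_col = "human_id", "zfish_id"
        else:
            raise ValueError("direction must be 'to_human' or 'to_zebrafish'")
        out: dict[str, list[str]] = {}
        for src, dst in self.frame[[src_col, dst_col]].itertuples(index=False):
            bucket = out.setdefault(src, [])
            if dst not in bucket:
                bucket.append(dst)
        return out


def load_orthology(path: str | Path) -> OrthologyTable:
    """Read an orthology TSV, honoring an optional ``#ns`` metadata line.

    The metadata line has the form ``#ns zfish=<namespace> human=<namespace>``
    and declares which namespace each column's identifiers live in.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    zfish_ns = human_ns = Namespace.SYMBOL
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#ns"):
                for token in line[3:].split():
                    key, _, val = token.partition("=")
                    if key == "zfish":
                        zfish_ns = Namespace.parse(val)
                    elif key == "human":
                        human_ns = Namespace.parse(val)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    return OrthologyTable(frame, zfish_ns=zfish_ns, human_ns=human_ns)


def write_orthology(table: OrthologyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#ns zfish={table.zfish_ns.value} human={table.human_ns.value}\n")
        table.frame.to_csv(fh, sep="\t", index=False)


def _expand(ids: Sequence[str], mapping: dict[str, list[str]], fold_case: bool = False):
    cleaned = _clean_ids(ids)
    mapped: list[tuple[str, str]] = []
    unmapped: list[str] = []
    one_to_many = 0
    for value in cleaned:
        key = value.lower() if fold_case else value
        targets = mapping.get(key)
        if targets:
            mapped.extend((value, t) for t in targets)
            if len(targets) > 1:
                one_to_many += 1
        else:
            unmapped.append(value)
    return mapped, unmapped, one_to_many


def convert_ids(
    ids: Iterable[str],
    from_ns: str | Namespace,
    to_ns: str | Namespace,
    table: MappingTable,
    keep_unmapped: bool = True,
    fold_case: bool = False,
) -> ConversionResult:
    """Convert identifiers between two namespaces through a mapping table.

    One-to-many relations emit every target (the caller deduplicates
    downstream).  Matching is exact after whitespace trimming; ``fold_case``
    opts into case-insensitive matching, which is off by default because
    zebrafish symbols are conventionally lowercase and silent case-folding
    can create false merges with human symbols.
    """
    from_ns = Namespace.parse(from_ns)
    to_ns = Namespace.parse(to_ns)
    cleaned = _clean_ids(ids)
    if from_ns == to_ns:
        return ConversionResult(
            mapped=[(v, v) for v in cleaned],
            unmapped=[],
            one_to_many_count=0,
            keep_unmapped=keep_unmapped,
        )
    mapping = table.multimap(from_ns, to_ns, fold_case=fold_case)
    mapped, unmapped, n_multi = _expand(cleaned, mapping, fold_case=fold_case)
    return ConversionResult(mapped, unmapped, n_multi, keep_unmapped=keep_unmapped)


def to_human(
    ids: Iterable[str], ortho: OrthologyTable, keep_unmapped: bool = True
) -> ConversionResult:
    """Map zebrafish genes to *all* of their human orthologs."""
    mapped, unmapped, n_multi = _expand(_clean_ids(ids), ortho.multimap("to_human"))
    return ConversionResult(mapped, unmapped, n_multi, keep_unmapped=keep_unmapped)


def to_zebrafish(
    ids: Iterable[str], ortho: OrthologyTable, keep_unmapped: bool = True
) -> ConversionResult:
    """Map human genes to *all* of their zebrafish orthologs (co-ortholog
    pairs from the teleost duplication both appear)."""
    mapped, unmapped, n_multi = _expand(_clean_ids(ids), ortho.multimap("to_zebrafish"))
    return ConversionResult(mapped, unmapped, n_multi, keep_unmapped=keep_unmapped)
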