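"""Ranked-lineage handling and cross-method taxonomy harmonization.

Metabarcoding taxonomy (PR2-style semicolon lineages) and microscopy
taxon lists report at different depths and with diverging nomenclature.
This module parses lineages into a fixed eight-rank frame, applies
user-supplied curation maps, lumps the centric diatom classes, restricts
records to the defined phytoplankton community, and computes taxon
overlap between methods.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "DIATOM_LUMP",
    "DEFAULT_WHITELIST",
    "DEFAULT_DROP_LABELS",
    "RankedLineage",
    "NameMap",
    "parse_lineage",
    "apply_name_map",
    "lump_diatom_classes",
    "apply_centrales_rule",
    "filter_phytoplankton",
    "rank_overlap",
    "read_name_map",
    "write_name_map",
]

#: The eight ranks kept throughout the pipeline, shallow to deep.
RANKS: tuple[str, ...] = (
    "supergroup",
    "division",
    "subdivision",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

UNASSIGNED = "unassigned"

#: Label of the lumped centric-diatom class.
DIATOM_LUMP = "Coscinodiscophyceae+Mediophyceae"

#: The fourteen classes defining the eukaryotic micro- and
#: nanophytoplankton community (centric diatoms lumped).
DEFAULT_WHITELIST: frozenset[str] = frozenset(
    {
        "Bacillariophyceae",
        DIATOM_LUMP,
        "Chlorodendrophyceae",
        "Chlorophyceae",
        "Chrysophyceae",
        "Coccolithophyceae",
        "Cryptophyceae",
        "Dictyochophyceae",
        "Dinophyceae",
        "Eustigmatophyceae",
        "Noctilucophyceae",
        "Pyramimonadophyceae",
        "Raphidophyceae",
        "Trebouxiophyceae",
    }
)

#: Microscopy catch-all categories that cannot be placed at class level.
DEFAULT_DROP_LABELS: frozenset[str] = frozenset({"unicells", "flagellates"})

_WS = re.compile(r"\s+")


def _clean(name: str) -> str:
    """Normalize whitespace in a taxon name; empty/NA becomes unassigned."""
    name = _WS.sub(" ", str(name)).strip()
    name = name.replace(" + ", "+")
    if name in ("", "nan", "NA", "None"):
        return UNASSIGNED
    return name


class LineageError(ValueError):
    """Raised for lineages that violate the rank-prefix rule."""


@dataclass(frozen=True)
class RankedLineage:
    """A taxon lineage on the fixed eight-rank frame.

    Ranks are assigned shallow-to-deep; once a rank is unassigned every
    deeper rank must be unassigned too (enforced at construction).
    """

    supergroup: str = UNASSIGNED
    division: str = UNASSIGNED
    subdivision: str = UNASSIGNED
    class_: str = UNASSIGNED
    order: str = UNASSIGNED
    family: str = UNASSIGNED
    genus: str = UNASSIGNED
    species: str = UNASSIGNED

    def __post_init__(self) -> None:
        seen_unassigned = False
        for rank in RANKS:
            name = self.get(rank)
            if name == UNASSIGNED:
                seen_unassigned = True
            elif seen_unassigned:
                raise LineageError(
                    f"rank '{rank}' is assigned ({name!r}) below an unassigned rank"
                )

    @staticmethod
    def _attr(rank: str) -> str:
        return "class_" if rank == "class" else rank

    def get(self, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return getattr(self, self._attr(rank))

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(self.get(r) for r in RANKS)

    @property
    def terminal_rank(self) -> str | None:
        """Deepest assigned rank, or None if fully unassigned."""
        deepest = None
        for rank in RANKS:
            if self.get(rank) != UNASSIGNED:
                deepest = rank
        return deepest

    @property
    def terminal_name(self) -> str:
        rank = self.terminal_rank
        return UNASSIGNED if rank is None else self.get(rank)

    def replace(self, **updates: str) -> "RankedLineage":
        fields = {self._attr(r): self.get(r) for r in RANKS}
        for rank, name in updates.items():
            fields[self._attr(rank)] = name
        return RankedLineage(**fields)

    def truncate(self, rank: str | None) -> "RankedLineage":
        """Keep ranks down to ``rank`` (inclusive); deeper ranks unassigned.

        ``rank=None`` returns a fully unassigned lineage.
        """
        if rank is None:
            return RankedLineage()
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        cut = RANKS.index(rank)
        fields = {}
        for i, r in enumerate(RANKS):
            fields[self._attr(r)] = self.get(r) if i <= cut else UNASSIGNED
        return RankedLineage(**fields)

    @classmethod
    def from_fields(cls, names, relaxed: bool = False) -> "RankedLineage":
        """Build from shallow-to-deep names (padded with unassigned).

        With ``relaxed=True`` a gap (assigned rank below an unassigned
        one) is repaired by clearing everything below the gap instead of
        raising; microscopy exports occasionally contain such records.
        """
        names = [_clean(n) for n in names][: len(RANKS)]
        names += [UNASSIGNED] * (len(RANKS) - len(names))
        if relaxed:
            out = []
            broken = False
            for n in names:
                if n == UNASSIGNED:
                    broken = True
                out.append(UNASSIGNED if broken else n)
            names = out
        return cls(**{cls._attr(r): n for r, n in zip(RANKS, names)})


def parse_lineage(lineage: str, source_ranks: tuple[str, ...] | None = None) -> RankedLineage:
    """Parse a semicolon-joined rank string into a :class:`RankedLineage`.

    PR2 v5 strings carry nine ranks (domain first); the leading domain is
    dropped. Shorter strings are mapped positionally onto the eight kept
    ranks and padded with ``unassigned``. ``source_ranks`` names the input
    fields explicitly when the source uses a different rank set; fields
    whose rank name is not one of the kept ranks are dropped.
    """
    fields = [f for f in str(lineage).split(";")]
    if len(fields) > 9:
        raise LineageError(f"lineage has {len(fields)} fields, at most 9 supported")
    if source_ranks is not None:
        if len(fields) > len(source_ranks):
            raise LineageError("more lineage fields than source_ranks names")
        by_rank = {r: f for r, f in zip(source_ranks, fields)}
        names = [by_rank.get(r, UNASSIGNED) for r in RANKS]
        return RankedLineage.from_fields(names)
    if len(fields) == 9:  # PR2 v5: domain;supergroup;...;species
        fields = fields[1:]
    return RankedLineage.from_fields(fields)


@dataclass
class NameMap:
    """Exact-match (rank, from_name) -> to_name substitutions.

    The map must be idempotent: applying it twice equals applying it
    once. A target name that is itself remapped to a different name at
    the same rank therefore makes the map invalid.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["rank", "from_name", "to_name"]))
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"rank", "from_name", "to_name"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"name map missing columns: {sorted(missing)}")
        bad = set(self.table["rank"]) - set(RANKS)
        if bad:
            raise ValueError(f"name map has unknown rank names: {sorted(bad)}")
        for rank, sub in self.table.groupby("rank"):
            m = dict(zip(sub["from_name"], sub["to_name"]))
            for src, dst in m.items():
                if dst in m and m[dst] != dst and dst != src:
                    raise ValueError(
                        f"name map not idempotent at rank {rank!r}: "
                        f"{src!r} -> {dst!r} -> {m[dst]!r}"
                    )

    def mapping(self, rank: str) -> dict[str, str]:
        sub = self.table[self.table["rank"] == rank]
        return dict(zip(sub["from_name"], sub["to_name"]))


def read_name_map(path) -> NameMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    prov = ""
    if "source" in df.columns:
        prov = ";".join(sorted(set(df["source"])))
    return NameMap(df[["rank", "from_name", "to_name"]], provenance=prov)


def write_name_map(name_map: NameMap, path) -> None:
    name_map.table.to_csv(path, sep="\t", index=False)


def _rank_cols(df: pd.DataFrame) -> list[str]:
    return [r for r in RANKS if r in df.columns]


def apply_name_map(lineages, name_map: NameMap):
    """Apply a :class:`NameMap` to lineages.

    Accepts a DataFrame with rank-named columns (returned as a new
    DataFrame) or an iterable of :class:`RankedLineage` (returned as a
    list). Unmapped names pass through unchanged; the operation is
    idempotent by the NameMap invariant.
    """
    if isinstance(lineages, pd.DataFrame):
        out = lineages.copy()
        for rank in _rank_cols(out):
            m = name_map.mapping(rank)
            if m:
                out[rank] = out[rank].map(lambda n: m.get(n, n))
        return out
    result = []
    for lin in lineages:
        updates = {}
        for rank in RANKS:
            m = name_map.mapping(rank)
            name = lin.get(rank)
            if name in m:
                updates[rank] = m[name]
        result.append(lin.replace(**updates) if updates else lin)
    return result


def lump_diatom_classes(obj):
    """Rewrite class Coscinodiscophyceae or Mediophyceae to the lumped label.

    Microscopy cannot separate unknown centric diatoms into the two
    classes, so both methods are compared on the lumped class. Accepts a
    :class:`RankedLineage`, a DataFrame with a ``class`` column, or a
    plain class name.
    """
    targets = {"Coscinodiscophyceae", "Mediophyceae"}
    if isinstance(obj, RankedLineage):
        if obj.get("class") in targets:
            return obj.replace(**{"class": DIATOM_LUMP})
        return obj
    if isinstance(obj, pd.DataFrame):
        out = obj.copy()
        if "class" in out.columns:
            out["class"] = out["class"].map(lambda c: DIATOM_LUMP if c in targets else c)
        return out
    return DIATOM_LUMP if obj in targets else obj


def apply_centrales_rule(df: pd.DataFrame) -> pd.DataFrame:
    """Assign order-level 'Centrales' records to the lumped diatom class.

    Monitoring microscopy reports unknown centric diatoms at the
    paraphyletic order Centrales without a class; they belong to the
    lumped centric-diatom class by construction.
    """
    out = df.copy()
    if "order" not in out.columns or "class" not in out.columns:
        return out
    mask = (out["order"] == "Centrales") & (out["class"] == UNASSIGNED)
    if mask.any():
        out.loc[mask, "class"] = DIATOM_LUMP
        for col in ("supergroup", "division", "subdivision"):
            if col in out.columns:
                out.loc[mask & (out[col] == UNASSIGNED), col] = {
                    "supergroup": "TSAR",
                    "division": "Stramenopiles",
                    "subdivision": "Gyrista",
                }[col]
    return out


def _terminal_names(df: pd.DataFrame) -> pd.Series:
    cols = _rank_cols(df)
    term = pd.Series(UNASSIGNED, index=df.index)
    for col in cols:  # shallow to deep; last assigned wins
        assigned = df[col] != UNASSIGNED
        term[assigned] = df.loc[assigned, col]
    return term


def filter_phytoplankton(
    records: pd.DataFrame,
    whitelist=DEFAULT_WHITELIST,
    drop_labels=DEFAULT_DROP_LABELS,
) -> tuple[pd.DataFrame, dict]:
    """Restrict records to the defined phytoplankton community.

    Records whose terminal taxon name is a catch-all label (default
    "unicells"/"flagellates") are removed first; then only records whose
    class is in the whitelist are kept. Returns the kept records and a
    report of counts per reason.
    """
    whitelist = set(whitelist)
    drop_labels = set(drop_labels)
    n_in = len(records)
    if n_in == 0:
        return records.copy(), {"n_input": 0, "n_kept": 0, "n_dropped_label": 0, "n_dropped_class": 0}
    term = _terminal_names(records)
    labeled = term.isin(drop_labels)
    kept = records[~labeled]
    in_whitelist = kept["class"].isin(whitelist) if "class" in kept.columns else pd.Series(False, index=kept.index)
    out = kept[in_whitelist].copy()
    report = {
        "n_input": n_in,
        "n_kept": len(out),
        "n_dropped_label": int(labeled.sum()),
        "n_dropped_class": int((~in_whitelist).sum()),
    }
    return out, report


def rank_overlap(taxa_a, taxa_b) -> tuple[int, int, int]:
    """Unique-to-A, unique-to-B and shared taxon counts at one rank.

    ``unassigned`` never counts as a taxon.
    """
    a = {t for t in taxa_a if t != UNASSIGNED}
    b = {t for t in taxa_b if t != UNASSIGNED}
    shared = a & b
    return len(a - b), len(b - a), len(shared)
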