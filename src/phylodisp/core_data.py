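"""Data model and I/O for the morphological matrix, character scheme and taxonomy.

The central object is the *morphomatrix*: a genus x character table of
unordered multistate characters in which a cell holds the **set** of states
realized within a genus (genus-level scoring spans within-genus variation,
so polymorphic cells are expected).  An empty cell means *unscored*, never
*state absent*: a genus missing data for a character is excluded from that
character's statistics rather than counted as lacking every state.

File dialects
-------------
* morphomatrix CSV: first column ``genus``, one column per character id;
  cells are semicolon-joined state ids (``"B04-3;B04-4"``), with ``""`` or
  ``"?"`` for missing.
* character scheme YAML: list of ``{id, category, label, states}`` entries.
  State ids follow the ``<character>-<number>`` convention (``"B04-3"``).
* taxonomy: a genus CSV (``genus,tribe``; empty tribe = orphan) and a tribe
  CSV (``tribe,lineage[,lineage_*][,wgd,rate_shift,n_species,n_genera,
  speciation,extinction,net_div]``), plus an optional long genome-size CSV
  (``tribe,genome_size_pg``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from phylodisp.errors import ParseError, ValidationError

MISSING_TOKENS = {"", "?", "NA", "nan"}

VALID_CATEGORIES = frozenset("ABCDEF")


@dataclass(frozen=True)
class Character:
    """One morphological character: an id, a category code (A-F, e.g.
    vegetative vs. flower vs. fruit characters), a human-readable label and
    an ordered list of state ids."""

    id: str
    category: str
    label: str
    states: tuple[str, ...]

    @property
    def k(self) -> int:
        """Number of states of this character."""
        return len(self.states)


class CharacterScheme:
    """Catalogue of characters and their states.

    Every state id belongs to exactly one character and every character has
    at least two states; category codes are restricted to A-F.
    """

    def __init__(self, characters: Iterable[Character]):
        self.characters: tuple[Character, ...] = tuple(characters)
        self._by_id: dict[str, Character] = {}
        self._state_owner: dict[str, str] = {}
        for ch in self.characters:
            if ch.id in self._by_id:
                raise ValidationError(f"duplicate character id {ch.id!r}")
            if ch.category not in VALID_CATEGORIES:
                raise ValidationError(
                    f"character {ch.id!r}: category {ch.category!r} not in A-F"
                )
            if ch.k < 2:
                raise ValidationError(f"character {ch.id!r} has {ch.k} state(s); need >= 2")
            self._by_id[ch.id] = ch
            for s in ch.states:
                if s in self._state_owner:
                    raise ValidationError(
                        f"state {s!r} appears in characters "
                        f"{self._state_owner[s]!r} and {ch.id!r}"
                    )
                self._state_owner[s] = ch.id

    def __len__(self) -> int:
        return len(self.characters)

    def __iter__(self):
        return iter(self.characters)

    def __contains__(self, character_id: str) -> bool:
        return character_id in self._by_id

    def __getitem__(self, character_id: str) -> Character:
        return self._by_id[character_id]

    @property
    def character_ids(self) -> list[str]:
        return [c.id for c in self.characters]

    @property
    def state_ids(self) -> list[str]:
        return [s for c in self.characters for s in c.states]

    @property
    def n_states(self) -> int:
        return len(self._state_owner)

    def owner(self, state_id: str) -> str:
        """Character id that ``state_id`` belongs to."""
        try:
            return self._state_owner[state_id]
        except KeyError:
            raise ValidationError(f"unknown state id {state_id!r}") from None

    # -- I/O ---------------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = [
            {
                "id": c.id,
                "category": c.category,
                "label": c.label,
                "states": list(c.states),
            }
            for c in self.characters
        ]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CharacterScheme":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, list):
            raise ParseError(f"{path}: expected a YAML list of characters")
        chars = []
        for entry in doc:
            try:
                chars.append(
                    Character(
                        id=str(entry["id"]),
                        category=str(entry["category"]),
                        label=str(entry.get("label", "")),
                        states=tuple(str(s) for s in entry["states"]),
                    )
                )
            except KeyError as exc:
                raise ParseError(f"{path}: character entry missing key {exc}") from None
        return cls(chars)


class MorphoMatrix:
    """Genus x character map of realized state sets.

    ``cells[(genus, character_id)]`` is a frozenset of state ids; an empty
    set encodes missing/unknown.  Cells never mix states from different
    characters.
    """

    def __init__(
        self,
        scheme: CharacterScheme,
        genera: Iterable[str],
        cells: Mapping[tuple[str, str], frozenset[str] | set[str]],
    ):
        self.scheme = scheme
        self.genera: list[str] = list(genera)
        if len(set(self.genera)) != len(self.genera):
            raise ValidationError("genus names are not unique")
        genus_set = set(self.genera)
        self.cells: dict[tuple[str, str], frozenset[str]] = {}
        for (genus, char_id), states in cells.items():
            if genus not in genus_set:
                raise ValidationError(f"cell for unknown genus {genus!r}")
            if char_id not in scheme:
                raise ValidationError(f"cell for unknown character {char_id!r}")
            fs = frozenset(states)
            for s in fs:
                if scheme.owner(s) != char_id:
                    raise ValidationError(
                        f"genus {genus!r}, character {char_id!r}: state {s!r} "
                        f"belongs to character {scheme.owner(s)!r}"
                    )
            if fs:
                self.cells[(genus, char_id)] = fs

    def states_of(self, genus: str, character_id: str) -> frozenset[str]:
        """Realized states (empty frozenset = missing)."""
        return self.cells.get((genus, character_id), frozenset())

    def is_scored(self, genus: str, character_id: str) -> bool:
        return (genus, character_id) in self.cells

    def to_frame(self) -> pd.DataFrame:
        """Wide string representation (semicolon-joined states, '' missing)."""
        data = {
            c.id: [
                ";".join(sorted(self.states_of(g, c.id))) for g in self.genera
            ]
            for c in self.scheme
        }
        return pd.DataFrame(data, index=pd.Index(self.genera, name="genus"))


def _parse_cell(raw: object, genus: str, char: Character, scheme: CharacterScheme) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return frozenset()
    text = str(raw).strip()
    if text in MISSING_TOKENS:
        return frozenset()
    states = set()
    for token in text.split(";"):
        token = token.strip()
        if not token:
            raise ParseError(
                f"genus {genus!r}, character {char.id!r}: malformed cell {text!r}"
            )
        if token not in scheme._state_owner:
            raise ValidationError(
                f"genus {genus!r}, character {char.id!r}: unknown state {token!r}"
            )
        if scheme.owner(token) != char.id:
            raise ValidationError(
                f"genus {genus!r}, character {char.id!r}: state {token!r} "
                f"belongs to character {scheme.owner(token)!r}"
            )
        states.add(token)
    return frozenset(states)


def read_morphomatrix(path: str | Path, scheme: CharacterScheme) -> MorphoMatrix:
    """Read a morphomatrix CSV and validate it against ``scheme``.

    The header must contain a ``genus`` column plus one column per character
    id known to the scheme; unknown columns are rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "genus" not in df.columns:
        raise ParseError(f"{path}: no 'genus' column")
    unknown = [c for c in df.columns if c != "genus" and c not in scheme]
    if unknown:
        raise ParseError(f"{path}: unknown character column(s) {unknown}")
    genera = df["genus"].tolist()
    cells: dict[tuple[str, str], frozenset[str]] = {}
    for col in df.columns:
        if col == "genus":
            continue
        char = scheme[col]
        for genus, raw in zip(genera, df[col]):
            states = _parse_cell(raw, genus, char, scheme)
            if states:
                cells[(genus, col)] = states
    return MorphoMatrix(scheme, genera, cells)


def write_morphomatrix(m: MorphoMatrix, path: str | Path) -> None:
    """Write the CSV dialect read by :func:`read_morphomatrix`."""
    m.to_frame().to_csv(path)


@dataclass
class TaxonomyTable:
    """Genus -> tribe assignment plus tribal metadata.

    ``genus_to_tribe`` maps genus to tribe, with ``None`` for orphan genera
    (genera of uncertain tribal placement; they are retained for genus-level
    statistics and excluded from tribal and lineage statistics).  Lineage
    assignment is defined per tribe; ``lineage_schemes`` may hold several
    alternative groupings (a 3-lineage default plus 4-/5-lineage variants).
    """

    genus_to_tribe: dict[str, str | None]
    lineage_schemes: dict[str, dict[str, str]]
    wgd: dict[str, bool | None] = field(default_factory=dict)
    rate_shift: dict[str, bool] = field(default_factory=dict)
    covariates: pd.DataFrame | None = None
    genome_sizes: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "lineage" not in self.lineage_schemes:
            raise ValidationError("lineage_schemes must include the default 'lineage' scheme")

    @property
    def tribes(self) -> list[str]:
        return sorted(self.lineage_schemes["lineage"])

    def genera_of(self, tribe: str) -> list[str]:
        return [g for g, t in self.genus_to_tribe.items() if t == tribe]

    def lineage_of(self, tribe: str, scheme: str = "lineage") -> str:
        try:
            mapping = self.lineage_schemes[scheme]
        except KeyError:
            raise ValidationError(f"unknown lineage scheme {scheme!r}") from None
        return mapping[tribe]

    def tribes_of_lineage(self, lineage: str, scheme: str = "lineage") -> list[str]:
        mapping = self.lineage_schemes[scheme]
        return sorted(t for t, ln in mapping.items() if ln == lineage)

    @property
    def orphans(self) -> list[str]:
        return sorted(g for g, t in self.genus_to_tribe.items() if t is None)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csvs(
        cls,
        genus_csv: str | Path,
        tribe_csv: str | Path,
        genome_size_csv: str | Path | None = None,
    ) -> "TaxonomyTable":
        gdf = pd.read_csv(genus_csv, dtype=str, keep_default_na=False)
        if not {"genus", "tribe"} <= set(gdf.columns):
            raise ParseError(f"{genus_csv}: need columns genus,tribe")
        genus_to_tribe = {
            row.genus: (row.tribe if row.tribe not in MISSING_TOKENS else None)
            for row in gdf.itertuples()
        }
        tdf = pd.read_csv(tribe_csv)
        if "tribe" not in tdf.columns or "lineage" not in tdf.columns:
            raise ParseError(f"{tribe_csv}: need columns tribe,lineage")
        tdf = tdf.set_index("tribe")
        lineage_schemes = {
            col: tdf[col].dropna().astype(str).to_dict()
            for col in tdf.columns
            if col == "lineage" or col.startswith("lineage_")
        }

        def _flag(col: str) -> dict:
            if col not in tdf.columns:
                return {}
            out = {}
            for tribe, v in tdf[col].items():
                out[tribe] = None if pd.isna(v) else bool(v)
            return out

        cov_cols = [
            c
            for c in ("n_species", "n_genera", "speciation", "extinction", "net_div")
            if c in tdf.columns
        ]
        covariates = tdf[cov_cols].copy() if cov_cols else None
        genome_sizes: dict[str, list[float]] = {}
        if genome_size_csv is not None:
            gs = pd.read_csv(genome_size_csv)
            for tribe, grp in gs.groupby("tribe"):
                genome_sizes[str(tribe)] = [float(v) for v in grp["genome_size_pg"]]
        return cls(
            genus_to_tribe=genus_to_tribe,
            lineage_schemes=lineage_schemes,
            wgd=_flag("wgd"),
            rate_shift={t: bool(v) for t, v in _flag("rate_shift").items() if v is not None},
            covariates=covariates,
            genome_sizes=genome_sizes,
        )

    def to_csvs(self, genus_csv: str | Path, tribe_csv: str | Path) -> None:
        pd.DataFrame(
            {
                "genus": list(self.genus_to_tribe),
                "tribe": [t if t is not None else "" for t in self.genus_to_tribe.values()],
            }
        ).to_csv(genus_csv, index=False)
        tribes = self.tribes
        out = pd.DataFrame(index=pd.Index(tribes, name="tribe"))
        for name, mapping in self.lineage_schemes.items():
            out[name] = [mapping.get(t) for t in tribes]
        if self.wgd:
            out["wgd"] = [self.wgd.get(t) for t in tribes]
        if self.rate_shift:
            out["rate_shift"] = [self.rate_shift.get(t, False) for t in tribes]
        if self.covariates is not None:
            out = out.join(self.covariates)
        out.to_csv(tribe_csv)


class TribalStateMatrix:
    """Tribe x state presence/absence matrix derived from genus scoring.

    ``presence`` is a 0/1 DataFrame (tribes x state ids); ``scored`` is a
    boolean DataFrame (tribes x character ids) marking whether at least one
    member genus was scored for the character — unscored (tribe, character)
    pairs have an all-zero presence row for that character's states and are
    treated as missing downstream, not as universal absence.
    """

    def __init__(self, presence: pd.DataFrame, scored: pd.DataFrame, scheme: CharacterScheme):
        self.presence = presence.astype(int)
        self.scored = scored.astype(bool)
        self.scheme = scheme
        missing_states = [s for s in scheme.state_ids if s not in presence.columns]
        if missing_states:
            raise ValidationError(f"presence matrix lacks columns for states {missing_states[:5]}...")

    @property
    def tribes(self) -> list[str]:
        return list(self.presence.index)

    def states_of(self, tribe: str, character_id: str) -> frozenset[str]:
        char = self.scheme[character_id]
        row = self.presence.loc[tribe, list(char.states)]
        return frozenset(s for s, v in row.items() if v)

    def to_csv(self, path: str | Path) -> None:
        self.presence.rename_axis("tribe").to_csv(path)


def aggregate_to_tribes(m: MorphoMatrix, tax: TaxonomyTable) -> TribalStateMatrix:
    """Derive the tribal presence/absence matrix from genus scoring.

    A state is present in a tribe iff at least one member genus exhibits it
    (set union over genera).  Orphan genera are excluded.  Tribes without a
    single scored genus for a character keep an all-zero row for that
    character's states and are flagged unscored.
    """
    tribes = [t for t in tax.tribes if tax.genera_of(t)]
    skipped = [t for t in tax.tribes if not tax.genera_of(t)]
    if skipped:
        warnings.warn(f"tribes with zero member genera excluded: {skipped}")
    state_ids = m.scheme.state_ids
    presence = pd.DataFrame(0, index=pd.Index(tribes, name="tribe"), columns=state_ids)
    scored = pd.DataFrame(
        False, index=pd.Index(tribes, name="tribe"), columns=m.scheme.character_ids
    )
    genus_set = set(m.genera)
    for tribe in tribes:
        members = [g for g in tax.genera_of(tribe) if g in genus_set]
        for char in m.scheme:
            union: set[str] = set()
            any_scored = False
            for g in members:
                states = m.states_of(g, char.id)
                if states:
                    any_scored = True
                    union |= states
            if any_scored:
                scored.loc[tribe, char.id] = True
                for s in union:
                    presence.loc[tribe, s] = 1
    return TribalStateMatrix(presence, scored, m.scheme)
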