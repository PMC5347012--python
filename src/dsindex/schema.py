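"""ROI feature schema: the ordered catalogue of morphometric measures.

The default schema mirrors a standard FreeSurfer tabulation: cortical
thickness and cortical gray-matter volume for the 34 Desikan-Killiany
parcels of each hemisphere (68 + 68 measures) plus 51 subcortical
segmentation volumes, for 187 measures in total.  The algorithms
downstream are dimension-agnostic; any schema with at least two entries
may be substituted.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

VALID_KINDS = ("thickness", "volume")
VALID_HEMISPHERES = ("left", "right", "bilateral", "none")

_DEFAULT_RESOURCE = "roi_schema_187.csv"


@dataclass(frozen=True)
class ROIEntry:
    """One morphometric measure: its name, kind and laterality."""

    name: str
    kind: str  # "thickness" [mm] or "volume" [mm^3]
    hemisphere: str  # left | right | bilateral | none

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown measure kind {self.kind!r} for {self.name!r}")
        if self.hemisphere not in VALID_HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere {self.hemisphere!r} for {self.name!r}"
            )


@dataclass(frozen=True)
class ROISchema:
    """Ordered, immutable catalogue of ROI measures.

    Order is significant: feature matrices place columns in schema order,
    and fitted models record a fingerprint of the schema they were
    trained against.
    """

    entries: tuple[ROIEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in schema: {dupes}")
        if len(self.entries) < 2:
            raise ValueError("schema must contain at least two features")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ROIEntry]:
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def kinds(self) -> list[str]:
        return [e.kind for e in self.entries]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in schema") from None

    def volume_mask(self) -> list[bool]:
        """True for volume-kind columns (the ones ICV adjustment touches)."""
        return [e.kind == "volume" for e in self.entries]

    def fingerprint(self) -> str:
        """Stable hash of the ordered (name, kind) sequence."""
        h = hashlib.sha256()
        for e in self.entries:
            h.update(f"{e.name}\t{e.kind}\n".encode())
        return h.hexdigest()[:16]

    def match(self, key: str) -> list[str]:
        """Expand a region key to the schema features it names.

        A key matches a feature if it equals the feature name exactly,
        or if the normalised key equals the feature's normalised region
        stem (hemisphere prefixes and measure-kind suffixes stripped).
        ``"hippocampus"`` therefore matches ``Left-Hippocampus`` and
        ``Right-Hippocampus``; ``"entorhinal"`` matches the four cortical
        entorhinal measures.
        """
        exact = [e.name for e in self.entries if e.name == key]
        if exact:
            return exact
        want = _normalise(key)
        hits = [e.name for e in self.entries if _stem(e.name) == want]
        if not hits:
            raise KeyError(f"region key {key!r} matches no schema feature")
        return hits

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "ROISchema":
        return cls(tuple(ROIEntry(n, k, h) for n, k, h in rows))

    @classmethod
    def from_file(cls, path) -> "ROISchema":
        """Read a schema file: CSV with header ``name,kind,hemisphere``."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = {"name", "kind", "hemisphere"} - set(reader.fieldnames or ())
            if missing:
                raise ValueError(f"schema file missing columns: {sorted(missing)}")
            rows = [(r["name"], r["kind"], r["hemisphere"]) for r in reader]
        return cls.from_rows(rows)


_ALIASES = {
    "inferiorlateralventricle": "inflatvent",
    "inferiorpartofthelateralventricle": "inflatvent",
}


def _normalise(key: str) -> str:
    k = re.sub(r"[^a-z0-9]", "", key.lower())
    return _ALIASES.get(k, k)


def _stem(name: str) -> str:
    """Region stem: drop hemisphere prefixes and kind suffixes, normalise."""
    s = name
    s = re.sub(r"^(lh_|rh_|Left-|Right-)", "", s)
    s = re.sub(r"_(thickness|volume)$", "", s)
    return _normalise(s)


def default_schema() -> ROISchema:
    """The packaged 187-measure schema (68 thickness + 68 + 51 volumes)."""
    ref = resources.files("dsindex.data").joinpath(_DEFAULT_RESOURCE)
    with resources.as_file(ref) as path:
        return ROISchema.from_file(path)
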