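"""Gene-set collections and GMT I/O."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


@dataclass
class GeneSetCollection:
    """Named gene sets; every set non-empty, names unique."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set {name!r}")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def read_gmt(gmt_path) -> GeneSetCollection:
    """Read a GMT file (name, description, members, tab-separated).

    Duplicate members within a set are de-duplicated; empty sets are dropped
    with a warning; a repeated set name is a hard error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    n_dropped = 0
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                warnings.warn(f"{gmt_path}:{lineno}: unreadable GMT line skipped")
                continue
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} at line {lineno}")
            members = frozenset(m for m in members if m)
            if not members:
                n_dropped += 1
                continue
            sets[name] = members
            descriptions[name] = desc
    if n_dropped:
        warnings.warn(f"{gmt_path}: dropped {n_dropped} empty set(s)")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
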