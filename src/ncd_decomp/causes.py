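"""The 20-group NCD cause-of-death partition.

All analyses run on 20 mutually exclusive, collectively exhaustive
groups of NCD causes: 16 named leading causes (or aetiologically
related groups) and 4 residual groups (other circulatory diseases,
other malignant neoplasms, other neuropsychiatric conditions, other
NCDs).  The assignment of detailed source cause codes to groups is
configuration, loaded from YAML; the 16 + 4 structure is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["CauseMap", "N_GROUPS", "RESIDUAL_GROUPS"]

N_GROUPS = 20
N_NAMED = 16
RESIDUAL_GROUPS = (
    "other_circulatory",
    "other_malignant_neoplasms",
    "other_neuropsychiatric",
    "other_ncds",
)


@dataclass(frozen=True)
class CauseMap:
    """Assignment of detailed cause codes to the 20 NCD cause groups.

    Attributes
    ----------
    groups
        Ordered group identifiers (16 named, then 4 residual).
    kind
        ``"named"`` or ``"residual"`` per group.
    sdg34
        Whether the group belongs to the SDG target 3.4 cause superset
        (cancers, cardiovascular diseases, chronic respiratory
        diseases, diabetes).
    code_to_group
        Detailed code -> group id.  Every code maps to exactly one
        group.
    """

    groups: tuple[str, ...]
    kind: dict[str, str]
    sdg34: dict[str, bool]
    code_to_group: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.groups) != N_GROUPS:
            raise ValueError(f"cause map must define exactly {N_GROUPS} groups, got {len(self.groups)}")
        named = [g for g in self.groups if self.kind[g] == "named"]
        residual = [g for g in self.groups if self.kind[g] == "residual"]
        if len(named) != N_NAMED or len(residual) != N_GROUPS - N_NAMED:
            raise ValueError(
                f"cause map must have {N_NAMED} named and {N_GROUPS - N_NAMED} residual groups, "
                f"got {len(named)} named and {len(residual)} residual"
            )
        if set(residual) != set(RESIDUAL_GROUPS):
            raise ValueError(f"residual groups must be {sorted(RESIDUAL_GROUPS)}, got {sorted(residual)}")
        targets = set(self.code_to_group.values())
        missing = targets - set(self.groups)
        if missing:
            raise ValueError(f"codes map to unknown groups: {sorted(missing)}")

    # -- lookups ------------------------------------------------------

    def group_of(self, code: str) -> str:
        try:
            return self.code_to_group[code]
        except KeyError:
            raise KeyError(
                f"cause code {code!r} is not assigned to any of the 20 cause groups"
            ) from None

    @property
    def sdg_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if self.sdg34[g])

    def index_of(self, group: str) -> int:
        return self.groups.index(group)

    # -- construction -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CauseMap":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def default(cls) -> "CauseMap":
        """The packaged identity map (group labels map to themselves)."""
        ref = resources.files("ncd_decomp").joinpath("data/cause_map.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "CauseMap":
        try:
            entries = raw["groups"]
        except (KeyError, TypeError):
            raise ValueError("cause map YAML must have a top-level 'groups' mapping") from None
        groups, kind, sdg34, code_to_group = [], {}, {}, {}
        for gid, spec in entries.items():
            groups.append(gid)
            kind[gid] = spec.get("kind", "named")
            sdg34[gid] = bool(spec.get("sdg34", False))
            for code in spec.get("codes", []):
                code = str(code)
                if code in code_to_group:
                    raise ValueError(
                        f"cause code {code!r} assigned to both "
                        f"{code_to_group[code]!r} and {gid!r}: groups must be mutually exclusive"
                    )
                code_to_group[code] = gid
        return cls(tuple(groups), kind, sdg34, code_to_group)

    def to_yaml(self, path: str | Path) -> None:
        by_group: dict[str, list[str]] = {g: [] for g in self.groups}
        for code, g in self.code_to_group.items():
            by_group[g].append(code)
        out = {
            "groups": {
                g: {"kind": self.kind[g], "sdg34": self.sdg34[g], "codes": sorted(by_group[g])}
                for g in self.groups
            }
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)
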