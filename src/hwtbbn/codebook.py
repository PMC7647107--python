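"""Survey codebook: variable definitions, roles, scales and state lists.

The codebook is the single source of truth for what a survey column means:
its role in the analysis (socio-economic characteristic, RANAS psychosocial
item, asset-checklist item, behaviour item, or id), its measurement scale,
and — for categorical variables — the ordered list of admissible states.
Column names in data files map one-to-one onto codebook variable names; no
fuzzy matching is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

ROLES = ("id", "sec", "ranas_item", "asset", "behaviour_item")
SCALES = ("likert_1_5", "binary_0_1", "categorical", "count")
RANAS_FACTORS = ("Risk", "Attitude", "Norm", "Ability", "Self-regulation")

#: number of sub-factor items each RANAS factor must own
_FACTOR_ITEM_COUNTS = {
    "Risk": 3,
    "Attitude": 3,
    "Norm": 3,
    "Ability": 3,
    "Self-regulation": 4,
}


class CodebookError(ValueError):
    """Raised when a codebook violates its structural invariants."""


@dataclass(frozen=True)
class VariableDef:
    """Definition of one survey variable."""

    name: str
    role: str
    scale: str = "categorical"
    factor: str | None = None
    states: tuple[str, ...] | None = None
    polarity: str = "positive"
    derived: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CodebookError(f"unknown role {self.role!r} for {self.name!r}")
        if self.scale not in SCALES:
            raise CodebookError(f"unknown scale {self.scale!r} for {self.name!r}")
        if self.role == "ranas_item" and self.factor not in RANAS_FACTORS:
            raise CodebookError(
                f"ranas_item {self.name!r} must name a RANAS factor, got {self.factor!r}"
            )
        if self.scale == "categorical" and not self.states:
            raise CodebookError(f"categorical variable {self.name!r} needs states")
        if self.polarity not in ("positive", "reverse"):
            raise CodebookError(f"bad polarity {self.polarity!r} for {self.name!r}")


@dataclass
class Codebook:
    """An ordered collection of :class:`VariableDef` with lookup helpers."""

    variables: list[VariableDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise CodebookError(f"duplicate variable names: {sorted(dupes)}")
        self._by_name = {v.name: v for v in self.variables}

    # -- lookup ------------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableDef:
        return self._by_name[name]

    def by_role(self, role: str) -> list[VariableDef]:
        return [v for v in self.variables if v.role == role]

    def items_for_factor(self, factor: str) -> list[VariableDef]:
        return [v for v in self.by_role("ranas_item") if v.factor == factor]

    @property
    def id_variable(self) -> str:
        ids = self.by_role("id")
        if len(ids) != 1:
            raise CodebookError("codebook must declare exactly one id variable")
        return ids[0].name

    def survey_columns(self) -> list[str]:
        """Columns expected in a raw survey file (derived nodes excluded)."""
        return [v.name for v in self.variables if not v.derived]

    # -- validation ---------------------------------------------------------
    def validate_default_structure(self) -> None:
        """Check the invariants of the full HWT instrument.

        Eight SEC variables, sixteen RANAS items distributed 3/3/3/3/4 over
        the five factors, at least one asset, five behaviour items.
        """
        sec = self.by_role("sec")
        if len(sec) != 8:
            raise CodebookError(f"expected 8 SEC variables, found {len(sec)}")
        for factor, want in _FACTOR_ITEM_COUNTS.items():
            got = len(self.items_for_factor(factor))
            if got != want:
                raise CodebookError(
                    f"factor {factor!r} must own {want} items, found {got}"
                )
        if not self.by_role("asset"):
            raise CodebookError("codebook declares no asset variables")
        if len(self.by_role("behaviour_item")) != 5:
            raise CodebookError("expected 5 behaviour items")

    # -- (de)serialization ----------------------------------------------------
    @classmethod
    def from_dict(cls, payload: dict) -> "Codebook":
        variables = []
        for entry in payload.get("variables", []):
            entry = dict(entry)
            states = entry.pop("states", None)
            variables.append(
                VariableDef(
                    name=str(entry.pop("name")),
                    role=entry.pop("role"),
                    scale=entry.pop("scale", "categorical"),
                    factor=entry.pop("factor", None),
                    states=tuple(str(s) for s in states) if states else None,
                    polarity=entry.pop("polarity", "positive"),
                    derived=bool(entry.pop("derived", False)),
                )
            )
        return cls(variables=variables)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            entry: dict = {"name": v.name, "role": v.role, "scale": v.scale}
            if v.factor:
                entry["factor"] = v.factor
            if v.states:
                entry["states"] = list(v.states)
            if v.polarity != "positive":
                entry["polarity"] = v.polarity
            if v.derived:
                entry["derived"] = True
            out.append(entry)
        return {"variables": out}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_codebook() -> Codebook:
    """The shipped codebook for the full HWT survey instrument."""
    text = resources.files("hwtbbn.data").joinpath("codebook.yaml").read_text()
    cb = Codebook.from_dict(yaml.safe_load(text))
    cb.validate_default_structure()
    return cb
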