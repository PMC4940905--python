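"""Dialect configuration loaded from the packaged rule table."""

from __future__ import annotations

from dataclasses import dataclass
from fnmatch import fnmatchcase
from functools import lru_cache
from importlib import resources

import yaml

from .errors import UnknownDialectError


@dataclass(frozen=True)
class TargetRule:
    path: str
    targets: tuple[str, ...]
    attributes: tuple[str, ...] | None = None

    def matches(self, path_tags: tuple[str, ...], attribute: str | None) -> bool:
        if self.attributes is not None:
            if attribute is None:
                return False
            if not any(fnmatchcase(attribute, pat) for pat in self.attributes):
                return False
        return _segments_match(tuple(self.path.split("/")), path_tags)


def _segments_match(pats: tuple[str, ...], segs: tuple[str, ...]) -> bool:
    if not pats:
        return not segs
    head, rest = pats[0], pats[1:]
    if head == "**":
        return any(_segments_match(rest, segs[i:]) for i in range(len(segs) + 1))
    return bool(segs) and fnmatchcase(segs[0], head) and _segments_match(rest, segs[1:])


@dataclass(frozen=True)
class Dialect:
    name: str
    identity_attributes: tuple[str, ...]
    name_attributes: tuple[str, ...]
    unordered_containers: frozenset[str]
    target_rules: tuple[TargetRule, ...]

    def classify_path(self, path_tags: tuple[str, ...], attribute: str | None) -> frozenset[str]:
        hits: set[str] = set()
        for rule in self.target_rules:
            if rule.matches(path_tags, attribute):
                hits.update(rule.targets)
        return frozenset(hits)


@lru_cache(maxsize=1)
def _load_config() -> dict:
    text = resources.files("comodiff.data").joinpath("rules.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=None)
def get_dialect(name: str) -> Dialect:
    cfg = _load_config()["dialects"]
    if name not in cfg:
        raise UnknownDialectError(
            f"unknown dialect {name!r}; expected one of {sorted(cfg)}")
    d = cfg[name]
    return Dialect(
        name=name,
        identity_attributes=tuple(d.get("identity_attributes", [])),
        name_attributes=tuple(d.get("name_attributes", [])),
        unordered_containers=frozenset(d.get("unordered_containers", [])),
        target_rules=tuple(
            TargetRule(
                path=r["path"],
                targets=tuple(r["targets"]),
                attributes=tuple(r["attributes"]) if "attributes" in r else None,
            )
            for r in d.get("target_rules", [])
        ),
    )


def dialect_names() -> list[str]:
    return sorted(_load_config()["dialects"])
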