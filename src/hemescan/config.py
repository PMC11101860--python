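"""Run configuration: every tunable parameter of the pipeline in one place.

A :class:`RunConfig` nests the per-stage parameter dataclasses and is
serialized verbatim into every report, so a prediction can always be
traced back to the exact cutoffs that produced it.  Config files are
YAML with the same nesting; unknown keys are rejected rather than
ignored.  Precedence: CLI flags > config file > defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .matcher import MatcherParams
from .scoring import ScoringParams
from .site_assessment import AssessmentParams
from .structure_io import DEFAULT_HEME_CODES
from .template_library import LibraryParams

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised on malformed configuration input."""


def _from_dict(cls, d: dict, where: str):
    fields = set(cls.__dataclass_fields__)
    unknown = set(d) - fields
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    library: LibraryParams = field(default_factory=LibraryParams)
    matcher: MatcherParams = field(default_factory=MatcherParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    assessment: AssessmentParams = field(default_factory=AssessmentParams)
    heme_codes: tuple[str, ...] = tuple(sorted(DEFAULT_HEME_CODES))
    top_n_sites: int = 5
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["heme_codes"] = list(self.heme_codes)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, sub_cls in (
            ("library", LibraryParams),
            ("matcher", MatcherParams),
            ("scoring", ScoringParams),
            ("assessment", AssessmentParams),
        ):
            if key in d:
                sub = d.pop(key)
                if not isinstance(sub, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                kwargs[key] = _from_dict(sub_cls, sub, key)
        if "heme_codes" in d:
            kwargs["heme_codes"] = tuple(str(c).upper() for c in d.pop("heme_codes"))
        for key in ("top_n_sites", "seed"):
            if key in d:
                kwargs[key] = int(d.pop(key))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(doc)
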