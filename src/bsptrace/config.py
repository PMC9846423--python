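"""Run configuration: every pipeline threshold in one serializable object.

Defaults are the published workflow's printed values: Mott error-probability
cutoff 0.001 (Phred 30), primary peak ratio 0.75, non-mixed fraction 0.75,
boundary runs 3-15, minimum aligned length 30 bp, minimum identity 75%,
minimum conversion rate 0.9, clone status bounds 20/80 and mixed-clone
partial fraction 20%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alignment import AlignParams
from .errors import ConfigError
from .grouped import CloneStatusParams, PlotParams
from .quality import QCParams
from .trimming import TrimParams


@dataclass
class RunConfig:
    """Aggregated, file-serializable configuration of a run."""

    trim: TrimParams = field(default_factory=TrimParams)
    align: AlignParams = field(default_factory=AlignParams)
    qc: QCParams = field(default_factory=QCParams)
    clone: CloneStatusParams = field(default_factory=CloneStatusParams)
    plot: PlotParams = field(default_factory=PlotParams)

    _SECTIONS = {"trim": TrimParams, "align": AlignParams, "qc": QCParams,
                 "clone": CloneStatusParams, "plot": PlotParams}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config file; unknown sections or keys are rejected."""
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - set(cls._SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for section, klass in cls._SECTIONS.items():
            entries = raw.get(section, {}) or {}
            if not isinstance(entries, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            known = {f.name for f in dataclasses.fields(klass)}
            bad = set(entries) - known
            if bad:
                raise ConfigError(
                    f"unknown keys in section {section!r}: {sorted(bad)}")
            try:
                kwargs[section] = klass(**entries)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid config section {section!r}: {exc}")
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        data = {name: dataclasses.asdict(getattr(self, name))
                for name in self._SECTIONS}
        for section in data.values():
            for k, v in list(section.items()):
                if isinstance(v, tuple):
                    section[k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        return Path(path)
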