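"""Threshold/schedule configuration and stderr logging setup."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import HBOND_CUTOFF, PLANARITY_TOLERANCE
from .scan import DEFAULT_SCHEDULES, ScanSchedule

__all__ = ["AnalysisConfig", "setup_logging"]


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the analysis.

    ``hbond_cutoff`` (Angstrom, inclusive) and ``planarity_tolerance``
    (degrees) govern the geometric classifications; the scan schedules give
    the per-phase round step sizes in degrees.
    """

    hbond_cutoff: float = HBOND_CUTOFF
    planarity_tolerance: float = PLANARITY_TOLERANCE
    schedules: dict[str, ScanSchedule] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "hbond_cutoff" in raw:
            cfg.hbond_cutoff = float(raw["hbond_cutoff"])
        if "planarity_tolerance" in raw:
            cfg.planarity_tolerance = float(raw["planarity_tolerance"])
        for phase, steps in (raw.get("schedules") or {}).items():
            cfg.schedules[phase] = ScanSchedule(tuple(float(s) for s in steps))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "hbond_cutoff": self.hbond_cutoff,
            "planarity_tolerance": self.planarity_tolerance,
            "schedules": {ph: list(s.steps) for ph, s in self.schedules.items()},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def setup_logging(verbosity: int = 0) -> None:
    """Route package logging to stderr; -v raises the level to DEBUG."""
    level = logging.DEBUG if verbosity > 0 else logging.INFO
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
    )
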