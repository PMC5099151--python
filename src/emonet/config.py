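"""Run configuration shared by the CLI subcommands.

A flat key=value text file can hold any of the fields; CLI flags override
file values.  Every stochastic step takes its seed from here, and the full
configuration is embedded in the outputs so a run can be reproduced from its
own artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

from .agreement import DEFAULT_N_BOOT, DEFAULT_THRESHOLD
from .io_matrices import DEFAULT_EMOTIONS, ValidationError

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    threshold: float = DEFAULT_THRESHOLD
    n_boot: int = DEFAULT_N_BOOT
    seed: int = 0
    aggregator: str = "mean"
    icc_form: str = "ICC2"
    emotions: tuple[str, ...] = DEFAULT_EMOTIONS
    top_k: int = 10
    formats: tuple[str, ...] = ("graphml", "gexf")

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")

    def metadata(self) -> dict:
        """Flat mapping embedded in every output file."""
        d = asdict(self)
        d["emotions"] = ",".join(self.emotions)
        d["formats"] = ",".join(self.formats)
        return d


_TUPLE_FIELDS = {"emotions", "formats"}
_FIELD_TYPES = {f.name: f for f in fields(RunConfig)}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat ``key = value`` config file; ``overrides`` win."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in _FIELD_TYPES:
            raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _TUPLE_FIELDS:
            values[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
        elif key in ("n_boot", "seed", "top_k"):
            values[key] = int(raw)
        elif key == "threshold":
            values[key] = float(raw)
        else:
            values[key] = raw
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
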