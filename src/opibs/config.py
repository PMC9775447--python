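"""Run-wide configuration: every tunable of the pipeline in one record.

Defaults are the package's standard operating point: 5-min epochs, ordinal
scale s=7 / word length m=5 / delay 1, classic-IBS word length 5, LF band
0.04–0.15 Hz and HF band 0.15–0.4 Hz, Burg order 16 on a 4 Hz resampled
tachogram, decision-tree screening with stratified 5-fold CV.  A config file
(YAML mapping or flat ``key = value`` lines) can override any field.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    segment_length_s: float = 300.0
    s: int = 7
    m: int = 5
    tau: int = 1
    ibs_d: int = 5
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    ar_order: int = 16
    resample_hz: float = 4.0
    classifier: str = "decision_tree"
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lf_band", "hf_band"):
            band = tuple(float(v) for v in getattr(self, name))
            object.__setattr__(self, name, band)
            if not band[0] < band[1]:
                raise ValueError(f"{name} must be (low, high) with low < high")
        if self.lf_band[1] > self.hf_band[0]:
            raise ValueError("LF and HF bands must be disjoint and ordered")
        if self.segment_length_s <= 0:
            raise ValueError("segment_length_s must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load overrides from YAML or flat ``key = value`` text."""
        text = Path(path).read_text()
        try:
            import yaml

            data = yaml.safe_load(text)
            if not isinstance(data, dict):
                raise ValueError
        except Exception:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("lf_band", "hf_band") and isinstance(value, str):
                value = tuple(float(v) for v in value.split(","))
            elif isinstance(value, str) and key != "classifier":
                value = float(value) if "." in value else int(value)
            kwargs[key] = value
        kwargs.update(overrides)
        return cls(**kwargs)
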