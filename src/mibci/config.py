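"""Run configuration: documented defaults, plain-text load/save, validation.

The file format is one `key: value` pair per line; `#` starts a comment.
Unknown keys and out-of-range values are rejected by name.  A single global
seed fans out to named sub-seeds inside the generator and the CV partitions
so every component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

from .synthgen import SynthConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # paradigm / decoding
    decoder_kind: str = "CSP/S"        # LAP/S | CSP/L | CSP/S
    n_pairs: int = 3                   # CSP filter pairs
    csp_window_s: float = 2.0          # sliding feature window (s)
    shrinkage: float = 0.05            # covariance diagonal loading
    ar_order: int = 16                 # Burg AR model order
    ar_window_s: float = 0.5           # AR estimation window (s)
    normalizer_horizon_s: float = 30.0
    # synthetic session (see SynthConfig for semantics)
    sampling_rate: float = 250.0
    erd_depth: float = 0.5
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    snr: float = 1.0
    mixing_sigma: float = 0.25
    artifact_rate: float = 0.0
    artifact_db: float = 40.0
    n_runs: int = 10
    trials_per_run: int = 25
    seed: int = 0
    # output
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.decoder_kind not in ("LAP/S", "CSP/L", "CSP/S"):
            raise ValueError(f"decoder_kind: unknown value {self.decoder_kind!r}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs: must be >= 1")
        self.synth_config()  # delegates range checks on generator fields

    def synth_config(self) -> SynthConfig:
        keys = {f.name for f in fields(SynthConfig)}
        d = {k: v for k, v in asdict(self).items() if k in keys}
        return SynthConfig(**d)


_BOOL = {"true": True, "false": False, "yes": True, "no": False}


def _coerce(raw: str, target):
    if isinstance(target, bool):
        if raw.lower() not in _BOOL:
            raise ValueError(f"expected boolean, got {raw!r}")
        return _BOOL[raw.lower()]
    return type(target)(raw)


def load_config(path) -> RunConfig:
    """Parse and validate a key/value config file; defaults fill gaps."""
    defaults = RunConfig()
    known = {f.name: getattr(defaults, f.name) for f in fields(RunConfig)}
    overrides = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"line {lineno}: expected 'key: value'")
            key, raw = (s.strip() for s in line.split(":", 1))
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            try:
                overrides[key] = _coerce(raw, known[key])
            except (TypeError, ValueError) as e:
                raise ValueError(f"config key {key!r}: {e}") from None
    return RunConfig(**overrides)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            fh.write(f"{key}: {val}\n")
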