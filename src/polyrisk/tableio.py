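"""TSV output with metadata headers, and config-file loading.

All tabular outputs are tab-separated with a single header row and optional
'#'-prefixed metadata lines (version, seed, parameters) so files stay both
human-readable and machine-parsable.  Model parameter sets can be loaded from
YAML or JSON mappings mirroring :class:`~polyrisk.models.ModelConfig`.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .models import ModelConfig

__all__ = ["write_tsv", "read_tsv", "load_config", "model_config_from_dict"]


def write_tsv(frame: pd.DataFrame, destination, metadata: dict | None = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed metadata lines.

    ``destination`` may be a path or an open text handle (e.g. sys.stdout).
    Metadata always includes the package version; pass e.g. ``{"seed": 1}``
    for stochastic outputs so runs are reproducible from the file alone.
    """
    meta = {"polyrisk_version": __version__}
    if metadata:
        meta.update(metadata)

    def _write(fh) -> None:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            _write(fh)


def read_tsv(source) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (frame, metadata)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    metadata: dict[str, str] = {}
    data_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
        else:
            data_lines.append(line)
    frame = pd.read_csv(io.StringIO("\n".join(data_lines)), sep="\t")
    return frame, metadata


def load_config(path) -> dict:
    """Load a YAML (or JSON — a YAML subset) mapping of model parameters."""
    text = Path(path).read_text(encoding="utf-8")
    config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config


def model_config_from_dict(config: dict) -> ModelConfig:
    """Build a :class:`ModelConfig` from a config mapping.

    Expected keys: ``model`` (or ``kind``), ``K``, ``n``, ``p`` and one of
    ``tau`` / ``h2l``.  Unknown keys are rejected so typos surface early.
    """
    config = dict(config)
    kind = config.pop("model", None) or config.pop("kind", None)
    if kind is None:
        raise ValueError("config must name the model kind under 'model' (or 'kind')")
    config.pop("kind", None)
    known = {"K", "n", "p", "tau", "h2l"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ModelConfig(kind=kind, **config)
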