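"""Readers, writers, and job-configuration validation.

FASTA is read through Biopython; record bodies may use per-nucleotide
material prefixes (e.g. ``rACGdAT``).  Job configurations are JSON; salt
concentrations are validated against the supported ranges of the declared
material and violations are reported with the range in the message.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ConfigError, SequenceError
from .model import MATERIALS, parse_sequence

#: supported salt ranges (molar) per single/mixed material scope
SALT_RANGES = {
    ("r",): {"sodium": (0.05, 1.0), "magnesium": (0.0, 0.0)},
    ("d",): {"sodium": (0.05, 1.1), "magnesium": (0.0, 0.2)},
    ("m",): {"sodium": (0.12, 0.12), "magnesium": (0.0, 0.0)},
    ("r", "d"): {"sodium": (0.12, 1.0), "magnesium": (0.0, 0.0)},
    ("r", "m"): {"sodium": (0.12, 0.12), "magnesium": (0.0, 0.0)},
}


def read_fasta(path, default_material: str = "r") -> list:
    """Ordered (name, annotated-nucleotide tuple) records; duplicate names
    and illegal letters are rejected with the record named."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        try:
            seq = parse_sequence(str(rec.seq), default_material)
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from None
        out.append((rec.id, seq))
    return out


def write_fasta(records, path) -> None:
    from .model import sequence_to_text

    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{sequence_to_text(seq)}\n")


@dataclass
class JobConfig:
    """Validated analysis/design job settings."""

    materials: tuple = ("r",)
    temperature: float = 310.15  # kelvin
    melt: tuple | None = None  # (t_min, t_step, t_max) in kelvin
    ensemble: str = "all"
    sodium: float = 1.0
    magnesium: float = 0.0
    parameters: str | None = None
    max_complex_size: int = 1
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    payload: dict = field(default_factory=dict)


def validate_config(raw: dict) -> JobConfig:
    """Apply defaults and validate ranges; rejected values cite the
    supported range in the message."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a JSON object")
    materials = tuple(raw.get("materials", ["r"]))
    for m in materials:
        if m not in MATERIALS:
            raise ConfigError(f"unknown material {m!r}")
    key = materials if materials in SALT_RANGES else tuple(sorted(materials))
    if key not in SALT_RANGES:
        raise ConfigError(f"unsupported material combination {materials}")
    ranges = SALT_RANGES[key]
    sodium = float(raw.get("sodium", 1.0))
    magnesium = float(raw.get("magnesium", 0.0))
    lo, hi = ranges["sodium"]
    if not (lo <= sodium <= hi):
        raise ConfigError(
            f"sodium {sodium} M outside supported range [{lo},{hi}] for "
            f"materials {'/'.join(MATERIALS[m] for m in materials)}"
        )
    lo, hi = ranges["magnesium"]
    if not (lo <= magnesium <= hi):
        raise ConfigError(
            f"magnesium {magnesium} M outside supported range [{lo},{hi}] "
            f"for materials {'/'.join(MATERIALS[m] for m in materials)}"
        )
    melt = raw.get("melt")
    if melt is not None:
        t_min, t_step, t_max = (float(v) for v in melt)
        if not (t_min <= t_max) or t_step <= 0:
            raise ConfigError(
                "melt requires t_min <= t_max and a positive step"
            )
        melt = (t_min, t_step, t_max)
    cfg = JobConfig(
        materials=materials,
        temperature=float(raw.get("temperature", 310.15)),
        melt=melt,
        ensemble=str(raw.get("ensemble", "all")),
        sodium=sodium,
        magnesium=magnesium,
        parameters=raw.get("parameters"),
        max_complex_size=int(raw.get("max_complex_size", 1)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
        payload={
            k: v
            for k, v in raw.items()
            if k
            not in {
                "materials", "temperature", "melt", "ensemble", "sodium",
                "magnesium", "parameters", "max_complex_size", "seed",
                "out_dir", "log_level",
            }
        },
    )
    if cfg.max_complex_size < 1:
        raise ConfigError("max_complex_size must be >= 1")
    return cfg


def load_config(path) -> JobConfig:
    return validate_config(json.loads(Path(path).read_text()))


def write_matrix_tsv(matrix: np.ndarray, path, labels=None) -> None:
    """TSV matrix writer with optional row/column labels (1-based indices
    otherwise)."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if labels is None:
        labels = [str(k + 1) for k in range(n)]
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
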