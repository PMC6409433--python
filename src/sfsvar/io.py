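"""SFS table file format and run configuration.

The SFS table is a tab-separated text dialect:

    #n=100
    #folded=0
    # any further '#' lines are comments
    locusA<TAB>5000<TAB>512<TAB>c_1<TAB>...<TAB>c_L
    locusB<TAB>5000<TAB>.<TAB>c_1<TAB>...<TAB>c_L

One row per locus: id, length in bp, substitution count to the outgroup
(``.`` when absent), then the L SFS counts — L = n-1 for unfolded
(derived-allele classes 1..n-1) or floor(n/2) for folded (minor-allele
classes).  Invariant classes 0 and n never appear.  read->write round-trips
byte-identically modulo comments.

Run configuration is YAML with ``model``, ``inference``, ``bootstrap`` and
``output`` blocks; unknown keys are rejected before any computation.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .likelihood import Locus, SFSDataset
from .spectrum import EpochModel, LocusModel, ModelSpec

__all__ = ["read_sfs_table", "write_sfs_table", "RunConfig"]


class SFSParseError(ValueError):
    pass


def read_sfs_table(path) -> SFSDataset:
    """Parse an SFS table file into an SFSDataset; errors name the offending line."""
    text = Path(path).read_text()
    n = folded = None
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("n="):
                n = _parse_int(body[2:], lineno, "n")
            elif body.startswith("folded="):
                v = _parse_int(body[7:], lineno, "folded")
                if v not in (0, 1):
                    raise SFSParseError(f"line {lineno}: folded must be 0 or 1")
                folded = bool(v)
            continue
        rows.append((lineno, line))
    if n is None or folded is None:
        raise SFSParseError("missing required header lines '#n=<int>' and '#folded=<0|1>'")
    L = (n // 2) if folded else (n - 1)

    loci, seen = [], set()
    for lineno, line in rows:
        parts = line.split("\t")
        if len(parts) != 3 + L:
            raise SFSParseError(
                f"line {lineno}: expected {3 + L} tab-separated fields "
                f"(id, m, x, {L} counts), got {len(parts)}")
        locus_id = parts[0]
        if locus_id in seen:
            raise SFSParseError(f"line {lineno}: duplicate locus id {locus_id!r}")
        seen.add(locus_id)
        m = _parse_int(parts[1], lineno, "m", positive=True)
        x = None if parts[2] == "." else _parse_int(parts[2], lineno, "x")
        counts = np.array([_parse_int(v, lineno, "count") for v in parts[3:]],
                          dtype=np.int64)
        loci.append(Locus(id=locus_id, m=m, counts=counts, x=x))
    if not loci:
        raise SFSParseError("no locus rows found")
    return SFSDataset(n=n, loci=tuple(loci), folded=folded)


def _parse_int(s: str, lineno: int, what: str, positive: bool = False) -> int:
    try:
        v = int(s)
    except ValueError:
        raise SFSParseError(f"line {lineno}: {what} must be a base-10 integer, got {s!r}")
    if v < 0 or (positive and v == 0):
        raise SFSParseError(f"line {lineno}: {what} must be "
                            f"{'positive' if positive else 'non-negative'}, got {v}")
    return v


def write_sfs_table(data: SFSDataset, path=None) -> Optional[str]:
    """Write a dataset in the SFS table dialect; returns the text when path is None."""
    buf = _io.StringIO()
    buf.write(f"#n={data.n}\n")
    buf.write(f"#folded={1 if data.folded else 0}\n")
    for loc in data.loci:
        x = "." if loc.x is None else str(loc.x)
        counts = "\t".join(str(int(v)) for v in loc.counts)
        buf.write(f"{loc.id}\t{loc.m}\t{x}\t{counts}\n")
    text = buf.getvalue()
    if path is None:
        return text
    Path(path).write_text(text)
    return None


_SCHEMA = {
    "model": {"n", "H", "tau", "shared_g", "reference", "divergence", "loci"},
    "inference": {"n_starts", "seed", "use_profile", "use_divergence",
                  "fit_epsilon", "gtol", "ftol", "maxiter"},
    "bootstrap": {"B", "level"},
    "constraints": {"ties", "pins"},
    "output": {"report", "table"},
}
_LOCUS_KEYS = {"id", "m", "theta", "f", "g", "epsilon"}


class RunConfig:
    """Validated YAML run configuration."""

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        for block, keys in raw.items():
            if block not in _SCHEMA:
                raise ValueError(f"unknown config block {block!r}")
            if keys is None:
                continue
            if not isinstance(keys, dict):
                raise ValueError(f"config block {block!r} must be a mapping")
            unknown = set(keys) - _SCHEMA[block]
            if unknown:
                raise ValueError(f"unknown keys in {block!r}: {sorted(unknown)}")
        for entry in (raw.get("model") or {}).get("loci") or []:
            unknown = set(entry) - _LOCUS_KEYS
            if unknown:
                raise ValueError(f"unknown locus keys: {sorted(unknown)}")
        self.raw = raw

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def model(self) -> dict:
        return self.raw.get("model") or {}

    @property
    def inference(self) -> dict:
        return self.raw.get("inference") or {}

    @property
    def bootstrap(self) -> dict:
        return self.raw.get("bootstrap") or {}

    @property
    def constraints(self) -> dict:
        return self.raw.get("constraints") or {}

    def build_model(self, default_loci=None) -> ModelSpec:
        """Instantiate the configured ModelSpec (used by simulate / expected-sfs)."""
        mb = self.model
        H = int(mb.get("H", 1))
        tau = tuple(float(v) for v in mb.get("tau", ()))
        epochs = EpochModel(H, tau)
        entries = mb.get("loci", default_loci)
        if not entries:
            raise ValueError("config model block must list loci")
        loci = tuple(
            LocusModel(theta=float(e.get("theta", 1e-3)), f=float(e.get("f", 1.0)),
                       g=tuple(float(v) for v in e.get("g", (1.0,) * (H - 1))),
                       m=int(e.get("m", 1000)), epsilon=float(e.get("epsilon", 0.0)),
                       id=str(e.get("id", f"locus{j}")))
            for j, e in enumerate(entries)
        )
        div = mb.get("divergence")
        divergence = (float(div["c"]), float(div["t"])) if div else None
        return ModelSpec(epochs=epochs, loci=loci,
                         shared_g=bool(mb.get("shared_g", False)),
                         divergence=divergence,
                         reference=int(mb.get("reference", 0)))

    def fit_template(self, data: SFSDataset) -> ModelSpec:
        """A structure-only template whose dimensions follow the data."""
        mb = self.model
        H = int(mb.get("H", 2))
        epochs = EpochModel(H, tuple(1.0 for _ in range(H - 1)))
        loci = tuple(
            LocusModel(theta=1e-3, f=1.0, g=(1.0,) * (H - 1), m=loc.m, id=loc.id)
            for loc in data.loci
        )
        div = mb.get("divergence")
        divergence = (1.0, 1.0) if div else None
        return ModelSpec(epochs=epochs, loci=loci,
                         shared_g=bool(mb.get("shared_g", False)),
                         divergence=divergence,
                         reference=int(mb.get("reference", 0)))
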