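"""Named, validated parameter sets and their on-disk JSON/YAML schema.

A :class:`ParameterSet` is an immutable mapping of strictly positive rate
constants attached to a model name.  Files carry a versioned ``schema`` key
so that readers can reject incompatible layouts.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import math

import yaml

from .errors import ParameterError, SchemaError

PARAMS_SCHEMA = "orbitempo/params/v1"

GENES = (1, 2, 3)

#: the eight per-gene rate stems of the full repressilator (24 rates total)
FULL_REPRESSILATOR_STEMS = (
    "alpha",        # transcription
    "sigma",        # translation
    "delta",        # mRNA degradation
    "gamma",        # protein (monomer) degradation
    "kdim_plus",    # dimerisation forward (2 monomers -> dimer)
    "kdim_minus",   # dimerisation backward
    "kprom_plus",   # promoter binding of the upstream dimer
    "kprom_minus",  # promoter unbinding
)

#: composed per-gene constants of the reduced repressilator descriptions
REDUCED_REPRESSILATOR_STEMS = ("r", "s", "delta", "gamma", "eta")


@dataclass(frozen=True)
class ParameterSet(Mapping):
    """Immutable mapping of named, strictly positive rate constants.

    Parameters
    ----------
    model:
        Registry name of the model the rates belong to
        (``bistable``, ``neural_tube``, ``repressilator_full``, ...).
    rates:
        Mapping from rate name to a strictly positive, finite float.
    """

    model: str
    rates: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for key, value in dict(self.rates).items():
            try:
                v = float(value)
            except (TypeError, ValueError):
                raise ParameterError(f"rate {key!r} is not a number: {value!r}")
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(
                    f"rate {key!r} must be strictly positive and finite, got {v}"
                )
            clean[key] = v
        object.__setattr__(self, "rates", clean)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self.rates[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.rates)

    def __len__(self) -> int:
        return len(self.rates)

    # convenience ----------------------------------------------------------
    def gene(self, stem: str, i: int) -> float:
        """Per-gene rate lookup, e.g. ``ps.gene("alpha", 2)`` -> ``alpha_2``."""
        return self.rates[f"{stem}_{i}"]

    def with_updates(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given rates replaced."""
        merged = {**self.rates, **updates}
        return ParameterSet(self.model, merged)

    def scaled(self, keys, factor: float) -> "ParameterSet":
        """Return a copy with ``rates[k] * factor`` for every key in *keys*."""
        if factor <= 0:
            raise ParameterError(f"scale factor must be positive, got {factor}")
        updates = {k: self.rates[k] * factor for k in keys}
        return self.with_updates(**updates)

    def to_dict(self) -> dict:
        return {"schema": PARAMS_SCHEMA, "model": self.model,
                "rates": dict(self.rates)}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ParameterSet":
        if not isinstance(payload, Mapping):
            raise SchemaError("parameter payload must be a mapping")
        schema = payload.get("schema")
        if schema != PARAMS_SCHEMA:
            raise SchemaError(
                f"unsupported parameter schema {schema!r}; expected {PARAMS_SCHEMA!r}"
            )
        for key in ("model", "rates"):
            if key not in payload:
                raise SchemaError(f"parameter payload missing key {key!r}")
        return cls(str(payload["model"]), dict(payload["rates"]))

    def save(self, path) -> None:
        """Write as JSON (``.json``) or YAML (anything else)."""
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ParameterSet":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(payload)


def per_gene(stem_values: Mapping[str, tuple]) -> dict:
    """Expand ``{"alpha": (a1, a2, a3)}`` into ``{"alpha_1": a1, ...}``."""
    rates = {}
    for stem, values in stem_values.items():
        if len(values) != len(GENES):
            raise ParameterError(f"{stem}: expected {len(GENES)} values")
        for i, v in zip(GENES, values):
            rates[f"{stem}_{i}"] = v
    return rates


def validate_full_repressilator(params: ParameterSet) -> None:
    """Check the full repressilator rate schema: exactly 24 named rates."""
    expected = {f"{stem}_{i}" for stem in FULL_REPRESSILATOR_STEMS for i in GENES}
    got = set(params)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise SchemaError(
            "full repressilator requires exactly the 24 rates "
            f"{sorted(expected)}; missing={missing} unexpected={extra}"
        )


def validate_reduced_repressilator(params: ParameterSet) -> None:
    expected = {f"{stem}_{i}" for stem in REDUCED_REPRESSILATOR_STEMS for i in GENES}
    got = set(params)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise SchemaError(
            "reduced repressilator requires exactly the composed rates "
            f"{sorted(expected)}; missing={missing} unexpected={extra}"
        )
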