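"""Series file I/O, fixture generation, and model/config (de)serialization.

Supported series formats: single-record FASTA (nominal DNA-like sequences),
plain token streams (one symbol per line), and one-column CSV.  Ordinal
ranges must always be declared explicitly — the natural order of categories
(e.g. SKC < FEW < SCT < BKN < OVC) is not lexicographic, so it is never
inferred by sorting labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from Bio import SeqIO

from .darma import DarmaSpec, simulate_darma
from .exceptions import InvalidModelError, UnknownSymbolError
from .fit import ModelFamily
from .markov import TransitionMatrix
from .presets import (
    CLOUDINESS_SERIES_LENGTH,
    DNA_SERIES_LENGTH,
    cloudiness_two_regime_model,
    dna_three_regime_model,
)
from .regime import RsDar1Spec, RsDarmaSpec, simulate_rs_darma
from .states import CategoricalRange, RangePartition

logger = logging.getLogger("rsdarma")

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in _FASTA_SUFFIXES:
        return "fasta"
    if path.suffix.lower() == ".csv":
        return "csv"
    return "tokens"


def read_series(path, format: Optional[str] = None,
                states: Optional[Sequence] = None, ordinal: bool = False,
                on_unknown: str = "error",
                record: Optional[Union[int, str]] = None):
    """Read a categorical series; returns (integer-coded array, range).

    FASTA input is lower-cased and validated against {a, c, g, t} unless a
    state set is declared; a multi-record file requires ``record`` (index or
    id).  Token/CSV input is one symbol per line (first CSV column).  If no
    state set is declared it is inferred as the sorted set of observed
    symbols (and ``ordinal`` must then be False).  Unknown symbols are a
    hard error naming the position, or dropped with a logged count when
    ``on_unknown='drop'``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if on_unknown not in ("error", "drop"):
        raise InvalidModelError("on_unknown must be 'error' or 'drop'")

    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise InvalidModelError(f"no FASTA records in {path}")
        if len(records) > 1 and record is None:
            raise InvalidModelError(
                f"{path} has {len(records)} records; pass record=<index or id>")
        if record is None:
            rec = records[0]
        elif isinstance(record, int):
            rec = records[record]
        else:
            by_id = {r.id: r for r in records}
            if record not in by_id:
                raise InvalidModelError(f"record {record!r} not in {sorted(by_id)}")
            rec = by_id[record]
        symbols = list(str(rec.seq).lower())
        if states is None:
            states = ("a", "c", "g", "t")
    elif fmt == "csv":
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if lines and lines[0].strip().lower() in ("state", "symbol", "value", "x"):
            lines = lines[1:]
        symbols = [ln.split(",")[0].strip() for ln in lines]
    elif fmt == "tokens":
        symbols = path.read_text().split()
    else:
        raise InvalidModelError(f"unknown format {fmt!r}")

    if not symbols:
        raise InvalidModelError(f"{path} contains no symbols")
    if states is None:
        if ordinal:
            raise InvalidModelError(
                "an ordinal range must be declared explicitly, never inferred")
        states = tuple(sorted(set(symbols)))
    rng = states if isinstance(states, CategoricalRange) else CategoricalRange(states, ordinal)

    index = {s: i for i, s in enumerate(rng.states)}
    coded, dropped = [], 0
    for pos, s in enumerate(symbols, start=1):
        i = index.get(s)
        if i is None:
            if on_unknown == "error":
                raise UnknownSymbolError(
                    f"unknown symbol {s!r} at position {pos} of {path}")
            dropped += 1
        else:
            coded.append(i)
    if dropped:
        logger.warning("dropped %d unknown symbols while reading %s", dropped, path)
    if not coded:
        raise InvalidModelError(f"no valid symbols in {path}")
    return np.asarray(coded, dtype=np.int64), rng


def write_series(path, x: np.ndarray, rng: CategoricalRange,
                 format: Optional[str] = None, fasta_id: str = "series") -> Path:
    """Write an integer-coded series; inverse of :func:`read_series` for
    valid inputs (bit-exact round trip)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    labels = [str(rng.states[i]) for i in np.asarray(x, dtype=int)]
    if fmt == "fasta":
        seq = "".join(labels)
        lines = [f">{fasta_id}"] + [seq[i: i + 70] for i in range(0, len(seq), 70)]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        path.write_text("state\n" + "\n".join(labels) + "\n")
    else:
        path.write_text("\n".join(labels) + "\n")
    return path


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def spec_to_dict(spec) -> dict:
    """JSON-able description of a model object."""
    if isinstance(spec, RsDar1Spec):
        return {
            "type": "rs_dar1",
            "variant": spec.variant,
            "states": list(spec.range.states),
            "ordinal": spec.range.ordinal,
            "blocks": [list(b) for b in spec.partition.blocks()],
            "phi_by_regime": spec.phi_by_regime.tolist(),
            "p_eps_by_regime": spec.p_eps_by_regime.tolist(),
            "delay": spec.delay,
        }
    if isinstance(spec, DarmaSpec):
        return {
            "type": "darma",
            "states": list(spec.range.states),
            "ordinal": spec.range.ordinal,
            "p": spec.p, "q": spec.q,
            "rho": spec.rho.tolist(),
            "p_eps": spec.p_eps.tolist(),
        }
    if isinstance(spec, TransitionMatrix):
        return {
            "type": "transition_matrix",
            "states": list(spec.range.states) if spec.range else None,
            "ordinal": spec.range.ordinal if spec.range else False,
            "P": spec.P.tolist(),
        }
    raise InvalidModelError(f"cannot serialize {type(spec).__name__}")


def spec_from_dict(d: dict):
    kind = d.get("type")
    if kind == "rs_dar1":
        rng = CategoricalRange(d["states"], d.get("ordinal", False))
        part = RangePartition.from_blocks(rng, d["blocks"])
        return RsDar1Spec(rng, part, d["variant"], d["phi_by_regime"],
                          d["p_eps_by_regime"], d.get("delay", 1))
    if kind == "darma":
        rng = CategoricalRange(d["states"], d.get("ordinal", False))
        return DarmaSpec(rng, d["p"], d["q"], d["rho"], d["p_eps"])
    if kind == "transition_matrix":
        rng = (CategoricalRange(d["states"], d.get("ordinal", False))
               if d.get("states") else None)
        return TransitionMatrix(np.asarray(d["P"], dtype=float), rng)
    raise InvalidModelError(f"unknown model type {kind!r}")


def save_model(spec, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(spec_to_dict(spec), indent=2) + "\n")
    return path


def load_model(path):
    return spec_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesFile:
    """A series on disk plus its sidecar metadata file."""

    path: Path
    sidecar: Path
    range: CategoricalRange
    T: int
    seed: int


def generate_fixture(profile, out, T: Optional[int] = None, seed: int = 0,
                     format: Optional[str] = None, burn_in: int = 500) -> SeriesFile:
    """Simulate a study-condition fixture and write it with a YAML sidecar.

    Profiles: ``'dna_like'`` — the three-regime DNA reference model,
    default T = 8419, FASTA; ``'cloudiness_like'`` — the two-regime
    cloudiness reference model, default T = 744, tokens; or any
    DarmaSpec/RsDar1Spec/RsDarmaSpec for custom conditions.  Output is
    bit-reproducible in (profile, T, seed).
    """
    if profile == "dna_like":
        spec = dna_three_regime_model()
        T = T or DNA_SERIES_LENGTH
        default_fmt = "fasta"
    elif profile == "cloudiness_like":
        spec = cloudiness_two_regime_model()
        T = T or CLOUDINESS_SERIES_LENGTH
        default_fmt = "tokens"
    elif isinstance(profile, (DarmaSpec, RsDar1Spec, RsDarmaSpec)):
        spec = profile
        if T is None:
            raise InvalidModelError("custom profiles need an explicit T")
        default_fmt = "tokens"
    else:
        raise InvalidModelError(
            "profile must be 'dna_like', 'cloudiness_like' or a model spec")

    out = Path(out)
    fmt = format or (default_fmt if out.suffix == "" else _infer_format(out))
    if out.suffix == "":
        out = out.with_suffix({"fasta": ".fasta", "csv": ".csv", "tokens": ".txt"}[fmt])
    if isinstance(spec, DarmaSpec):
        x = simulate_darma(spec, T, burn_in=burn_in, seed=seed)
    else:
        x = simulate_rs_darma(spec, T, burn_in=burn_in, seed=seed)
    write_series(out, x, spec.range, fmt)

    sidecar = out.with_suffix(out.suffix + ".meta.yaml")
    meta = {
        "profile": profile if isinstance(profile, str) else "custom",
        "T": int(T), "seed": int(seed), "burn_in": int(burn_in),
        "format": fmt,
        "states": list(spec.range.states),
        "ordinal": bool(spec.range.ordinal),
        "model": spec_to_dict(spec) if not isinstance(spec, RsDarmaSpec) else {
            "type": "rs_darma", "p": spec.p, "q": spec.q,
            "blocks": [list(b) for b in spec.partition.blocks()],
            "rho_by_regime": spec.rho_by_regime.tolist(),
            "p_eps_by_regime": spec.p_eps_by_regime.tolist(),
            "delay": spec.delay,
        },
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return SeriesFile(out, sidecar, spec.range, int(T), int(seed))


# ---------------------------------------------------------------------------
# selection config
# ---------------------------------------------------------------------------

def parse_partition(rng: CategoricalRange, text: str) -> RangePartition:
    """Parse 'a,g|c|t'-style block syntax into a partition."""
    blocks = [[s.strip() for s in block.split(",") if s.strip()]
              for block in text.split("|")]
    return RangePartition.from_blocks(rng, blocks)


def _family_from_dict(rng: CategoricalRange, d: dict) -> ModelFamily:
    kind = d["family"]
    part = parse_partition(rng, d["partition"]) if "partition" in d else None
    return ModelFamily(kind, part, int(d.get("delay", 1)))


def load_selection_config(path):
    """Load a YAML selection config.

    Keys: ``states`` (list, required), ``ordinal`` (bool), ``candidates``
    (list of {family, partition?, delay?}), ``criterion`` ('aic'|'bic'),
    ``restarts``, ``seed``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    rng = CategoricalRange(cfg["states"], cfg.get("ordinal", False))
    candidates = [_family_from_dict(rng, d) for d in cfg["candidates"]]
    return {
        "range": rng,
        "candidates": candidates,
        "criterion": cfg.get("criterion", "bic"),
        "restarts": int(cfg.get("restarts", 10)),
        "seed": int(cfg.get("seed", 0)),
    }
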