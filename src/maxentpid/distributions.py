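"""Discrete joint distributions over a target and three sources.

The central object is :class:`JointDistribution`, a finite probability mass
function over quadruples ``(t, x, y, z)`` where ``t`` is the target symbol and
``x, y, z`` are the three source symbols.  Everything downstream — the
constrained mutual-information minimizations, the decomposition identities,
the bivariate hierarchy — consumes this object or the pairwise marginals
derived from it via :func:`marginal_triple`.

All information functionals are reported in bits (log base 2).  Terms with
zero mass are skipped, never evaluated, implementing ``0 * log 0 = 0`` by
continuity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Hashable, Iterable, Mapping

__all__ = [
    "DistributionError",
    "NegativeMassError",
    "NotNormalizedError",
    "EmptyDistributionError",
    "MalformedRecordError",
    "DuplicateOutcomeError",
    "JointDistribution",
    "MarginalTriple",
    "validate",
    "marginal",
    "marginal_triple",
    "entropy",
    "mutual_information",
    "read_distribution",
    "write_distribution",
]

#: canonical variable order
VARIABLES = ("T", "X", "Y", "Z")

_NORM_TOL = 1e-12


class DistributionError(ValueError):
    """Base class for invalid probability mass functions."""


class NegativeMassError(DistributionError):
    """Some outcome carries negative mass."""


class NotNormalizedError(DistributionError):
    """Total mass deviates from 1 beyond tolerance."""


class EmptyDistributionError(DistributionError):
    """No outcome carries positive mass."""


class MalformedRecordError(DistributionError):
    """A serialized record could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateOutcomeError(DistributionError):
    """The same (t, x, y, z) outcome appears twice in a stream."""


def _label_key(label: Hashable):
    # opaque symbols are ordered by the string form of their text; tuples
    # (product symbols) recurse component-wise so that e.g. ('a','b') sorts
    # lexicographically in its components
    if isinstance(label, tuple):
        return (1, tuple(_label_key(c) for c in label))
    return (0, str(label))


def sorted_labels(labels: Iterable[Hashable]) -> tuple:
    """Stable total order on opaque labels (string order of their text form)."""
    return tuple(sorted(set(labels), key=_label_key))


@dataclass(frozen=True)
class JointDistribution:
    """A finite pmf over quadruples ``(t, x, y, z)``.

    Parameters
    ----------
    mass
        Mapping from outcome quadruple to probability.  Outcomes with exactly
        zero mass are permitted on input but dropped by :func:`validate`.

    Attributes
    ----------
    alphabet_t, alphabet_x, alphabet_y, alphabet_z
        The ordered label sets, derived from the support unless supplied.
    """

    mass: Mapping[tuple, float]
    alphabet_t: tuple = field(default=())
    alphabet_x: tuple = field(default=())
    alphabet_y: tuple = field(default=())
    alphabet_z: tuple = field(default=())

    def __post_init__(self):
        mass = dict(self.mass)
        for outcome in mass:
            if not (isinstance(outcome, tuple) and len(outcome) == 4):
                raise MalformedRecordError(
                    f"outcome {outcome!r} is not a (t, x, y, z) quadruple"
                )
        object.__setattr__(self, "mass", mass)
        support = [k for k, v in mass.items() if v > 0]
        derived = [sorted_labels(k[i] for k in support) for i in range(4)]
        for name, given, auto in zip(
            ("alphabet_t", "alphabet_x", "alphabet_y", "alphabet_z"),
            (self.alphabet_t, self.alphabet_x, self.alphabet_y, self.alphabet_z),
            derived,
        ):
            if given:
                missing = set(auto) - set(given)
                if missing:
                    raise DistributionError(
                        f"labels {missing!r} in support but not in declared {name}"
                    )
                object.__setattr__(self, name, tuple(given))
            else:
                object.__setattr__(self, name, auto)

    # -- convenience -------------------------------------------------------
    @property
    def support(self) -> list[tuple]:
        """Outcomes with strictly positive mass, in deterministic order."""
        return sorted((k for k, v in self.mass.items() if v > 0), key=_outcome_key)

    def total_mass(self) -> float:
        return math.fsum(self.mass.values())

    def __len__(self) -> int:
        return sum(1 for v in self.mass.values() if v > 0)

    def items(self):
        return self.mass.items()

    def __getitem__(self, outcome: tuple) -> float:
        return self.mass.get(outcome, 0.0)


def _outcome_key(outcome: tuple):
    return tuple(_label_key(c) for c in outcome)


@dataclass(frozen=True)
class MarginalTriple:
    """The three pairwise (target, source) marginals that define the feasible
    polytope of the minimizations: every admissible joint ``Q`` must reproduce
    ``Q(T,X) = pxt``, ``Q(T,Y) = pyt`` and ``Q(T,Z) = pzt``."""

    pxt: Mapping[tuple, float]
    pyt: Mapping[tuple, float]
    pzt: Mapping[tuple, float]

    def __post_init__(self):
        targets = None
        for name, m in (("pxt", self.pxt), ("pyt", self.pyt), ("pzt", self.pzt)):
            total = math.fsum(m.values())
            if abs(total - 1.0) > _NORM_TOL * 10:
                raise NotNormalizedError(f"{name} sums to {total!r}, not 1")
            tm: dict = {}
            for (t, _s), p in m.items():
                tm[t] = tm.get(t, 0.0) + p
            if targets is None:
                targets = tm
            else:
                keys = set(targets) | set(tm)
                for t in keys:
                    if abs(targets.get(t, 0.0) - tm.get(t, 0.0)) > 1e-10:
                        raise DistributionError(
                            "pairwise marginals imply inconsistent target marginals"
                        )

    def target_marginal(self) -> dict:
        out: dict = {}
        for (t, _x), p in self.pxt.items():
            out[t] = out.get(t, 0.0) + p
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def validate(d: JointDistribution | Mapping[tuple, float], tol: float = 1e-9) -> JointDistribution:
    """Check invariants and return a cleaned copy of *d*.

    Outcomes with exactly zero mass are removed; if the total mass deviates
    from 1 by less than *tol* the masses are renormalized to sum to exactly 1.

    Raises
    ------
    NegativeMassError
        if any mass is negative.
    NotNormalizedError
        if ``|total - 1| >= tol``.
    EmptyDistributionError
        if no outcome has positive mass.
    """
    if not isinstance(d, JointDistribution):
        d = JointDistribution(d)
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    neg = [k for k, v in d.mass.items() if v < 0]
    if neg:
        raise NegativeMassError(f"negative mass at outcome {neg[0]!r}")
    cleaned = {k: v for k, v in d.mass.items() if v > 0}
    if not cleaned:
        raise EmptyDistributionError("empty distribution: no outcome has positive mass")
    total = math.fsum(cleaned.values())
    if abs(total - 1.0) >= max(tol, _NORM_TOL):
        raise NotNormalizedError(f"not normalized: total mass is {total!r}")
    if total != 1.0:
        cleaned = {k: v / total for k, v in cleaned.items()}
    return JointDistribution(cleaned)


_VAR_INDEX = {v: i for i, v in enumerate(VARIABLES)}


def marginal(d: JointDistribution, which: Iterable[str]) -> dict:
    """Marginal pmf of *d* over the variables named in *which*.

    The result is keyed by tuples holding the retained symbols in canonical
    (T, X, Y, Z) order; a single retained variable still yields 1-tuples.
    """
    which = set(which)
    if not which:
        raise ValueError("empty selection: at least one of T, X, Y, Z required")
    unknown = which - set(VARIABLES)
    if unknown:
        raise ValueError(f"unknown variables {sorted(unknown)!r}")
    idx = [i for i, v in enumerate(VARIABLES) if v in which]
    out: dict = {}
    for outcome, p in d.mass.items():
        if p == 0.0:
            continue
        key = tuple(outcome[i] for i in idx)
        out[key] = out.get(key, 0.0) + p
    return out


def marginal_triple(d: JointDistribution) -> MarginalTriple:
    """The three pairwise (target, source) marginals of *d*."""
    def pair(i: int) -> dict:
        out: dict = {}
        for outcome, p in d.mass.items():
            if p == 0.0:
                continue
            key = (outcome[0], outcome[i])
            out[key] = out.get(key, 0.0) + p
        return out

    return MarginalTriple(pxt=pair(1), pyt=pair(2), pzt=pair(3))


def entropy(pmf: Mapping) -> float:
    """Shannon entropy of *pmf* in bits; zero-mass terms are skipped."""
    return -math.fsum(p * math.log2(p) for p in pmf.values() if p > 0)


def mutual_information(d: JointDistribution, sources: Iterable[str]) -> float:
    """``MI(T; S) = H(T) + H(S) - H(T, S)`` in bits, for a nonempty source
    subset ``S`` of {X, Y, Z}."""
    sources = set(sources)
    if not sources:
        raise ValueError("empty source set")
    if "T" in sources or sources - {"X", "Y", "Z"}:
        raise ValueError(f"sources must be a subset of X, Y, Z; got {sorted(sources)!r}")
    h_t = entropy(marginal(d, {"T"}))
    h_s = entropy(marginal(d, sources))
    h_ts = entropy(marginal(d, sources | {"T"}))
    return h_t + h_s - h_ts


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TABLE_HEADER = ["t", "x", "y", "z", "p"]


def _format_mass(p: float) -> str:
    return format(float(p), ".17g")  # 17 significant digits round-trip binary64 exactly


def write_distribution(d: JointDistribution, stream: IO[str], format: str = "table") -> None:
    """Serialize *d* to *stream* in the ``table`` (TSV) or ``structured``
    (JSON) dialect.  Labels are written as strings; masses as decimal text
    that round-trips exactly."""
    if format == "table":
        stream.write("\t".join(_TABLE_HEADER) + "\n")
        for outcome in d.support:
            t, x, y, z = (str(c) for c in outcome)
            stream.write(f"{t}\t{x}\t{y}\t{z}\t{_format_mass(d.mass[outcome])}\n")
    elif format == "structured":
        records = [
            {"t": str(k[0]), "x": str(k[1]), "y": str(k[2]), "z": str(k[3]),
             "p": d.mass[k]}
            for k in d.support
        ]
        json.dump({"dist": records}, stream, indent=1)
        stream.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_distribution(stream: IO[str], format: str = "table") -> JointDistribution:
    """Parse a distribution from *stream*; inverse of :func:`write_distribution`
    up to label stringification.  Raises :class:`MalformedRecordError` with a
    line number on bad records and :class:`DuplicateOutcomeError` on repeated
    outcomes; normalization issues are delegated to :func:`validate`."""
    mass: dict = {}
    if format == "table":
        lines = stream.read().splitlines()
        if not lines:
            raise MalformedRecordError("empty stream", line=1)
        header = lines[0].split("\t")
        if [h.strip().lower() for h in header] != _TABLE_HEADER:
            raise MalformedRecordError(
                f"expected header {'	'.join(_TABLE_HEADER)!r}, got {lines[0]!r}", line=1
            )
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise MalformedRecordError(
                    f"expected 5 tab-separated fields, got {len(parts)}", line=lineno
                )
            try:
                p = float(parts[4])
            except ValueError as exc:
                raise MalformedRecordError(f"bad mass {parts[4]!r}", line=lineno) from exc
            outcome = tuple(parts[:4])
            if outcome in mass:
                raise DuplicateOutcomeError(f"duplicate outcome {outcome!r} at line {lineno}")
            mass[outcome] = p
    elif format == "structured":
        try:
            payload = json.load(stream)
        except json.JSONDecodeError as exc:
            raise MalformedRecordError(f"invalid JSON: {exc}", line=exc.lineno) from exc
        if not isinstance(payload, dict) or "dist" not in payload:
            raise MalformedRecordError("expected a top-level map with a 'dist' list")
        for i, rec in enumerate(payload["dist"]):
            try:
                outcome = (str(rec["t"]), str(rec["x"]), str(rec["y"]), str(rec["z"]))
                p = float(rec["p"])
            except (KeyError, TypeError, ValueError) as exc:
                raise MalformedRecordError(f"bad record #{i}: {rec!r}") from exc
            if outcome in mass:
                raise DuplicateOutcomeError(f"duplicate outcome {outcome!r} (record #{i})")
            mass[outcome] = p
    else:
        raise ValueError(f"unknown format {format!r}")
    return validate(JointDistribution(mass))
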