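"""Average mutual information (AMI) profiles and their expanded variants.

A DNA sequence is mapped into a feature vector built from the empirical
marginal nucleotide distribution ``p0`` and the empirical joint distribution
``pk`` of nucleotide pairs separated by a lag of ``k`` bases:

* **AMI** — one value per lag, the mutual information (in bits by default)
  between positions ``n`` and ``n + k``::

      AMI_k = sum_{X,Y} pk(X,Y) * log( pk(X,Y) / (p0(X) * p0(Y)) )

  ``AMI_k`` is a Kullback-Leibler divergence between the proper
  distributions ``pk`` and ``p0 ⊗ p0`` and is therefore nonnegative.

* **eAMI** ("expanded AMI") — the 16 raw pair probabilities ``pk(X,Y)``
  per lag, concatenated over lags.

* **eaAMI** ("expanded adjusted AMI") — the 16 individual summands of
  ``AMI_k`` per lag; per lag they sum to ``AMI_k``.

The modeled alphabet is ``A, C, G, T``; any other letter is treated as
ambiguous and dropped from the counts (a pair is dropped if either member
is ambiguous).  Pairing is linear, not circular, so a sequence of length
``L`` contributes at most ``L - k`` pairs at lag ``k``.

Component ordering is frozen: lag-major, and within each lag the first
nucleotide ``X`` cycles over ``A, C, G, T`` as the outer index and the
second nucleotide ``Y`` as the inner index.  Trained models rely on this
ordering being stable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "ProfileError",
    "MarginalDistribution",
    "JointDistribution",
    "ProfileVector",
    "PROFILE_KINDS",
    "encode_sequence",
    "estimate_marginal",
    "estimate_joint",
    "ami_profile",
    "eami_profile",
    "eaami_profile",
    "profile",
    "profile_matrix",
    "component_names",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

BASES = "ACGT"
PROFILE_KINDS = ("AMI", "eAMI", "eaAMI")

# byte -> base index; -1 marks an ambiguous letter. Lowercase is accepted
# (sequences are canonicalized to uppercase by mapping both cases).
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class ProfileError(ValueError):
    """Raised for invalid profile inputs (empty alphabet, bad lag, ...)."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0, C=1, G=2, T=3, ambiguous=-1."""
    if len(seq) == 0:
        raise ProfileError("no-valid-bases: empty sequence")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode_sequence(str(seq))


@dataclass(frozen=True)
class MarginalDistribution:
    """Empirical single-nucleotide distribution ``p0`` over A, C, G, T."""

    probs: np.ndarray  # shape (4,), sums to 1

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))


@dataclass(frozen=True)
class JointDistribution:
    """Empirical lagged pair distribution ``pk`` (4x4, rows = first base)."""

    lag: int
    probs: np.ndarray  # shape (4, 4), sums to 1

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))


@dataclass(frozen=True)
class ProfileVector:
    """A sequence's AMI, eAMI or eaAMI feature vector.

    ``values`` has length ``max_lag`` for kind ``AMI`` and ``16 * max_lag``
    for the expanded kinds, in the canonical lag-major / X-outer / Y-inner
    ordering.  ``log_base`` records the logarithm base used for the
    information-weighted kinds (2 = bits).
    """

    kind: str
    max_lag: int
    values: np.ndarray
    log_base: float = 2.0

    def __post_init__(self):
        if self.kind not in PROFILE_KINDS:
            raise ProfileError(f"unknown profile kind {self.kind!r}")
        vals = np.asarray(self.values, dtype=float)
        expected = self.max_lag if self.kind == "AMI" else 16 * self.max_lag
        if vals.shape != (expected,):
            raise ProfileError(
                f"{self.kind} profile with max_lag={self.max_lag} must have "
                f"{expected} components, got shape {vals.shape}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def component_names(self) -> list[str]:
        return component_names(self.kind, self.max_lag)


def component_names(kind: str, max_lag: int) -> list[str]:
    """Canonical component names: ``k{lag}`` or ``k{lag}_{X}{Y}``."""
    if kind == "AMI":
        return [f"k{k}" for k in range(1, max_lag + 1)]
    return [
        f"k{k}_{x}{y}"
        for k in range(1, max_lag + 1)
        for x in BASES
        for y in BASES
    ]


# ---------------------------------------------------------------------------
# estimation


def estimate_marginal(seq) -> MarginalDistribution:
    """Estimate ``p0`` by counting unambiguous bases.

    Ambiguous letters are excluded from numerator and denominator, so the
    result is a proper distribution over A, C, G, T.
    """
    codes = _as_codes(seq)
    valid = codes[codes >= 0]
    if valid.size == 0:
        raise ProfileError("no-valid-bases: sequence has no A/C/G/T letters")
    counts = np.bincount(valid, minlength=4).astype(float)
    return MarginalDistribution(counts / counts.sum())


def estimate_joint(seq, k: int) -> JointDistribution:
    """Estimate ``pk`` from the at most ``L - k`` linear pairs at lag ``k``.

    A pair is counted only when both members are unambiguous.
    """
    codes = _as_codes(seq)
    L = codes.shape[0]
    if not 1 <= k <= L - 1:
        raise ProfileError(f"invalid-lag: k={k} outside [1, {L - 1}]")
    x, y = codes[:-k], codes[k:]
    valid = (x >= 0) & (y >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ProfileError(f"no-valid-pairs: no unambiguous pair at lag {k}")
    pair = x[valid].astype(np.intp) * 4 + y[valid]
    counts = np.bincount(pair, minlength=16).astype(float)
    return JointDistribution(k, (counts / n).reshape(4, 4))


# ---------------------------------------------------------------------------
# profiles


def _adjusted_terms(joint: np.ndarray, p0: np.ndarray, log_base: float) -> np.ndarray:
    """The 4x4 matrix pk * log(pk / (p0 p0)), with 0*log(.) := 0.

    Cells with ``pk > 0`` necessarily have both marginals positive (the
    bases occur in the sequence), so the ratio is well defined wherever
    it is needed.
    """
    terms = np.zeros((4, 4))
    mask = joint > 0
    denom = np.outer(p0, p0)
    terms[mask] = joint[mask] * (
        np.log(joint[mask] / denom[mask]) / np.log(log_base)
    )
    return terms


def ami_profile(seq, max_lag: int, log_base: float = 2.0) -> ProfileVector:
    """AMI profile: one mutual-information value per lag ``1..max_lag``."""
    codes = _as_codes(seq)
    p0 = estimate_marginal(codes).probs
    vals = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        joint = estimate_joint(codes, k).probs
        vals[k - 1] = _adjusted_terms(joint, p0, log_base).sum()
    return ProfileVector("AMI", max_lag, vals, log_base)


def eami_profile(seq, max_lag: int) -> ProfileVector:
    """eAMI profile: raw lagged pair probabilities, 16 per lag."""
    codes = _as_codes(seq)
    vals = np.empty(16 * max_lag)
    for k in range(1, max_lag + 1):
        vals[16 * (k - 1) : 16 * k] = estimate_joint(codes, k).probs.ravel()
    return ProfileVector("eAMI", max_lag, vals)


def eaami_profile(seq, max_lag: int, log_base: float = 2.0) -> ProfileVector:
    """eaAMI profile: the 16 information-weighted summands per lag."""
    codes = _as_codes(seq)
    p0 = estimate_marginal(codes).probs
    vals = np.empty(16 * max_lag)
    for k in range(1, max_lag + 1):
        joint = estimate_joint(codes, k).probs
        vals[16 * (k - 1) : 16 * k] = _adjusted_terms(joint, p0, log_base).ravel()
    return ProfileVector("eaAMI", max_lag, vals, log_base)


def profile(seq, kind: str, max_lag: int, log_base: float = 2.0) -> ProfileVector:
    """Dispatch to :func:`ami_profile`, :func:`eami_profile` or :func:`eaami_profile`."""
    if kind == "AMI":
        return ami_profile(seq, max_lag, log_base)
    if kind == "eAMI":
        return eami_profile(seq, max_lag)
    if kind == "eaAMI":
        return eaami_profile(seq, max_lag, log_base)
    raise ProfileError(f"unknown profile kind {kind!r}")


def profile_matrix(
    seqs: Iterable, kind: str, max_lag: int, log_base: float = 2.0
) -> np.ndarray:
    """Stack profiles of many sequences into an (n, dim) feature matrix."""
    rows = [profile(s, kind, max_lag, log_base).values for s in seqs]
    if not rows:
        raise ProfileError("no sequences given")
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# tab-separated export with a JSON sidecar describing the feature space


def write_profiles_tsv(
    path,
    matrix: np.ndarray,
    kind: str,
    max_lag: int,
    ids: Sequence[str] | None = None,
    log_base: float = 2.0,
) -> None:
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    names = component_names(kind, max_lag)
    if matrix.shape[1] != len(names):
        raise ProfileError(
            f"matrix has {matrix.shape[1]} columns, expected {len(names)}"
        )
    if ids is None:
        ids = [f"seq{i}" for i in range(matrix.shape[0])]
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for sid, row in zip(ids, matrix):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"kind": kind, "max_lag": max_lag, "log_base": log_base})
    )


def read_profiles_tsv(path) -> tuple[np.ndarray, dict, list[str]]:
    """Read a profile matrix written by :func:`write_profiles_tsv`.

    Returns ``(matrix, metadata, ids)``.
    """
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    ids: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = component_names(meta["kind"], meta["max_lag"])
        if header[1:] != expected:
            raise ProfileError("profile TSV header does not match its sidecar")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return np.array(rows, dtype=float), meta, ids
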