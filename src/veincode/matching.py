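"""Minimum-Hamming-distance multi-template matching.

At enrollment a subject stores the binary codes of its first N images (a
:class:`TemplateSet`).  A probe code is scored against a subject as

    score = min_n hamming(probe, template_n) / L

i.e. the smallest Hamming distance to any enrolled template, normalized by
codeword length.  Keeping several templates per subject shrinks genuine
scores (the min over a superset can only decrease) while leaving impostor
scores essentially unchanged.  The probe is accepted iff its score is <=
the decision threshold DT (the boundary accepts).

Codes are matched positionally: no shift/rotation search is attempted, so
the matcher relies on the block pooling in :mod:`veincode.features` for its
(limited) tolerance to translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import VeinCode

__all__ = [
    "TemplateSet",
    "IncompatibleCodesError",
    "InvalidEnrollmentError",
    "hamming",
    "match_score",
    "verify",
]


class IncompatibleCodesError(ValueError):
    """Codes of unequal length cannot be compared."""


class InvalidEnrollmentError(ValueError):
    """A template set must contain at least one code."""


@dataclass(frozen=True)
class TemplateSet:
    """Enrolled codes of one subject; all codes share one length L."""

    subject_id: str
    codes: tuple = field(default=())

    def __post_init__(self) -> None:
        codes = tuple(self.codes)
        object.__setattr__(self, "codes", codes)
        if not codes:
            raise InvalidEnrollmentError(f"subject {self.subject_id!r}: empty template set")
        L = len(codes[0])
        for c in codes:
            if not isinstance(c, VeinCode):
                raise TypeError("templates must be VeinCode instances")
            if len(c) != L:
                raise IncompatibleCodesError(
                    f"subject {self.subject_id!r}: template lengths differ ({len(c)} vs {L})"
                )

    @property
    def n_templates(self) -> int:
        return len(self.codes)

    @property
    def code_length(self) -> int:
        return len(self.codes[0])


def hamming(x: VeinCode, y: VeinCode) -> int:
    """Number of differing bit positions between two equal-length codes."""
    if len(x) != len(y):
        raise IncompatibleCodesError(f"code lengths differ: {len(x)} vs {len(y)}")
    # XOR of the packed payloads, then popcount; byte-padding bits are zero
    # in both operands and cannot contribute.
    return int(np.bitwise_count(x.packed() ^ y.packed()).sum())


def match_score(probe: VeinCode, templates: TemplateSet) -> float:
    """min_n hamming(probe, x(n)) / L -- in [0, 1], 0 iff an exact match."""
    if len(probe) != templates.code_length:
        raise IncompatibleCodesError(
            f"probe length {len(probe)} != template length {templates.code_length}"
        )
    best = min(hamming(probe, t) for t in templates.codes)
    return best / len(probe)


def verify(probe: VeinCode, templates: TemplateSet, dt: float) -> bool:
    """Accept/reject decision: accept iff match_score <= dt."""
    if not 0.0 <= dt <= 1.0:
        raise ValueError(f"decision threshold must be in [0, 1], got {dt}")
    return match_score(probe, templates) <= dt


def pack_codes(codes: Sequence[VeinCode]) -> np.ndarray:
    """Stack codes of equal length into an (n, ceil(L/8)) packed byte matrix.

    Internal fast path for bulk scoring (see :mod:`veincode.evaluation`).
    """
    if not codes:
        raise InvalidEnrollmentError("no codes to pack")
    L = len(codes[0])
    for c in codes:
        if len(c) != L:
            raise IncompatibleCodesError("cannot pack codes of unequal length")
    return np.stack([c.packed() for c in codes])


def min_hamming_scores(probes_packed: np.ndarray, templates_packed: np.ndarray, length: int) -> np.ndarray:
    """Vectorized match scores of many probes against one template set.

    ``probes_packed`` is (n_probes, nbytes), ``templates_packed`` is
    (n_templates, nbytes); returns an (n_probes,) float array of
    min-Hamming scores normalized by ``length``.
    """
    xor = probes_packed[:, None, :] ^ templates_packed[None, :, :]
    dists = np.bitwise_count(xor).sum(axis=2, dtype=np.int64)
    return dists.min(axis=1) / length
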