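"""Verification protocol: genuine/impostor trials, FAR/FRR, EER, rates at DT.

The protocol enrolls the first N samples of every subject as templates and
uses the remaining samples as probes.  Each probe yields

* one genuine (intra-instance, 1:1) trial against its own subject's
  template set, and
* one impostor (inter-instance, 1:N) trial against every other subject's
  full template set (min over that subject's N templates),

so a dataset of ``K`` subjects with ``s_k`` samples each produces
``sum_k (s_k - N)`` genuine trials and ``n_genuine * (K - 1)`` impostor
trials.  For 210 subjects x 12 samples at N=6 that is 1260 genuine and
263,340 impostor trials; for 492 x 12 at N=6, 2952 and 1,449,432.

Error rates at a threshold t (acceptance is score <= t, consistent with
:func:`veincode.matching.verify`):

* FAR(t) -- fraction of impostor scores <= t (non-decreasing in t);
* FRR(t) -- fraction of genuine scores  > t (non-increasing in t).

The EER is the common value at the crossing FAR = FRR, located by linear
interpolation on a threshold grid (1001 points in [0, 1] by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import BlockSpec, encode_image
from .matching import min_hamming_scores, pack_codes

__all__ = [
    "ProtocolError",
    "EvalReport",
    "RecognitionRates",
    "run_protocol",
    "score_protocol",
    "far_frr",
    "eer",
    "recognition_rates",
]

DEFAULT_THRESHOLDS = np.linspace(0.0, 1.0, 1001)


class ProtocolError(ValueError):
    """Dataset shape incompatible with the requested protocol."""


class EvaluationError(ValueError):
    """Score sets are empty or malformed."""


@dataclass
class RecognitionRates:
    """Recognition rates at one decision threshold DT."""

    dt: float
    n_genuine: int
    false_rejects: int          # genuine trials with score > DT
    intra_rate: float           # fraction of genuine trials accepted, %
    n_impostor: int
    false_accepts: int          # impostor trials with score <= DT
    inter_rate: float           # fraction of impostor trials rejected, %


@dataclass
class EvalReport:
    """Scores and error curves of one protocol run."""

    n_templates: int
    spec: BlockSpec | None
    genuine_scores: np.ndarray
    impostor_scores: np.ndarray
    genuine_ids: list            # (subject_id, sample_idx) per genuine trial
    thresholds: np.ndarray = field(default=None)
    far: np.ndarray = field(default=None)
    frr: np.ndarray = field(default=None)
    eer: float = field(default=None)
    eer_threshold: float = field(default=None)

    @property
    def n_genuine(self) -> int:
        return int(self.genuine_scores.size)

    @property
    def n_impostor(self) -> int:
        return int(self.impostor_scores.size)

    def to_dict(self) -> dict:
        """JSON-serializable summary (scores omitted, curves included)."""
        return {
            "n_templates": self.n_templates,
            "block_spec": str(self.spec) if self.spec is not None else None,
            "n_genuine_trials": self.n_genuine,
            "n_impostor_trials": self.n_impostor,
            "eer": float(self.eer),
            "eer_threshold": float(self.eer_threshold),
        }


def far_frr(
    genuine_scores: np.ndarray,
    impostor_scores: np.ndarray,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray]:
    """FAR and FRR sampled on a threshold grid.

    FAR(t) = P(impostor score <= t), FRR(t) = P(genuine score > t).
    """
    g = np.sort(np.asarray(genuine_scores, dtype=np.float64))
    i = np.sort(np.asarray(impostor_scores, dtype=np.float64))
    if g.size == 0 or i.size == 0:
        raise EvaluationError("need at least one genuine and one impostor score")
    t = np.asarray(thresholds, dtype=np.float64)
    far = np.searchsorted(i, t, side="right") / i.size
    frr = 1.0 - np.searchsorted(g, t, side="right") / g.size
    return far, frr


def eer(far: np.ndarray, frr: np.ndarray, thresholds: np.ndarray) -> tuple[float, float]:
    """Equal error rate and its threshold, by linear interpolation.

    ``far - frr`` is non-decreasing on the grid; the EER is the common
    value where it crosses zero.  If FAR equals FRR over an interval of
    grid points, the midpoint of that interval is used.
    """
    far = np.asarray(far, dtype=np.float64)
    frr = np.asarray(frr, dtype=np.float64)
    t = np.asarray(thresholds, dtype=np.float64)
    d = far - frr
    idx = np.flatnonzero(d >= 0)
    if idx.size == 0:  # FAR never reaches FRR on the grid; report endpoint
        return float((far[-1] + frr[-1]) / 2), float(t[-1])
    i = int(idx[0])
    if d[i] == 0.0:
        j = i
        while j + 1 < d.size and d[j + 1] == 0.0:
            j += 1
        k = (i + j) // 2
        mid = (i + j) % 2  # even interval: take midpoint value of the two
        value = (far[k] + far[k + mid]) / 2
        thr = (t[k] + t[k + mid]) / 2
        return float(value), float(thr)
    if i == 0:
        return float((far[0] + frr[0]) / 2), float(t[0])
    # linear interpolation of the sign change on [t[i-1], t[i]]
    w = d[i - 1] / (d[i - 1] - d[i])
    thr = t[i - 1] + w * (t[i] - t[i - 1])
    fa = far[i - 1] + w * (far[i] - far[i - 1])
    fr = frr[i - 1] + w * (frr[i] - frr[i - 1])
    return float((fa + fr) / 2), float(thr)


def recognition_rates(report: EvalReport, dt: float) -> RecognitionRates:
    """Intra/inter recognition rates (in percent) and false counts at DT."""
    if not 0.0 <= dt <= 1.0:
        raise ValueError(f"decision threshold must be in [0, 1], got {dt}")
    g = report.genuine_scores
    i = report.impostor_scores
    false_rejects = int(np.count_nonzero(g > dt))
    false_accepts = int(np.count_nonzero(i <= dt))
    return RecognitionRates(
        dt=dt,
        n_genuine=g.size,
        false_rejects=false_rejects,
        intra_rate=100.0 * (g.size - false_rejects) / g.size,
        n_impostor=i.size,
        false_accepts=false_accepts,
        inter_rate=100.0 * (i.size - false_accepts) / i.size,
    )


def score_protocol(
    codes_by_subject: Mapping[str, Sequence],
    n_templates: int,
    spec: BlockSpec | None = None,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> EvalReport:
    """Run the template/probe protocol on pre-computed codes.

    ``codes_by_subject`` maps subject id to its ordered list of VeinCodes;
    the first ``n_templates`` codes of each subject are enrolled, the rest
    are probes.
    """
    if n_templates < 1:
        raise ProtocolError("n_templates must be >= 1")
    subjects = list(codes_by_subject)
    if len(subjects) < 2:
        raise ProtocolError("protocol needs at least two subjects")
    for sid in subjects:
        if len(codes_by_subject[sid]) <= n_templates:
            raise ProtocolError(
                f"subject {sid!r} has {len(codes_by_subject[sid])} samples; "
                f"needs more than N={n_templates}"
            )

    template_packs = {}
    probe_codes, probe_subject, genuine_ids = [], [], []
    for sid in subjects:
        codes = list(codes_by_subject[sid])
        template_packs[sid] = pack_codes(codes[:n_templates])
        for k, c in enumerate(codes[n_templates:], start=n_templates):
            probe_codes.append(c)
            probe_subject.append(sid)
            genuine_ids.append((sid, k))

    L = len(probe_codes[0])
    probes_packed = pack_codes(probe_codes)
    probe_subject = np.asarray(probe_subject, dtype=object)

    genuine = np.empty(len(probe_codes), dtype=np.float64)
    impostor_chunks = []
    for sid in subjects:
        scores = min_hamming_scores(probes_packed, template_packs[sid], L)
        own = probe_subject == sid
        genuine[own] = scores[own]
        impostor_chunks.append(scores[~own])
    impostor = np.concatenate(impostor_chunks)

    far, frr = far_frr(genuine, impostor, thresholds)
    eer_value, eer_thr = eer(far, frr, thresholds)
    return EvalReport(
        n_templates=n_templates,
        spec=spec,
        genuine_scores=genuine,
        impostor_scores=impostor,
        genuine_ids=genuine_ids,
        thresholds=np.asarray(thresholds, dtype=np.float64),
        far=far,
        frr=frr,
        eer=eer_value,
        eer_threshold=eer_thr,
    )


def run_protocol(
    dataset: Mapping[str, Sequence[np.ndarray]],
    n_templates: int,
    spec: BlockSpec,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> EvalReport:
    """Encode every image, then run the template/probe protocol.

    ``dataset`` maps subject id to its ordered list of grayscale images;
    all images must share one size so the codes are comparable.
    """
    shapes = {np.asarray(img).shape[:2] for imgs in dataset.values() for img in imgs}
    if len(shapes) > 1:
        raise ProtocolError(f"images have mixed sizes: {sorted(shapes)}")
    codes = {
        sid: [encode_image(img, spec) for img in imgs] for sid, imgs in dataset.items()
    }
    return score_protocol(codes, n_templates, spec=spec, thresholds=thresholds)
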