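"""Text serialization of vein codes and score tables.

The ``veincode`` text format is one header line followed by one record per
image::

    #veincode v1 block=3x8 neighbors=cw-tl-v1
    <image-id> TAB <L> TAB <hex payload>

The payload is the code's bits packed MSB-first and zero-padded to a whole
byte, rendered as uppercase hex (so the 4-bit code ``1111`` becomes
``F0``).  The header pins the block spec and the neighbour-walk convention:
codes are only comparable within one convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .features import NEIGHBOR_CONVENTION, BlockSpec, VeinCode

__all__ = [
    "FORMAT_VERSION",
    "serialize_code",
    "parse_code_line",
    "header_line",
    "parse_header",
    "write_codes",
    "read_codes",
    "write_scores_csv",
]

FORMAT_VERSION = "v1"


class CodeFormatError(ValueError):
    """Malformed veincode file or record."""


def serialize_code(code: VeinCode, image_id: str) -> str:
    """One record line: ``<id> TAB <L> TAB <hex payload>``."""
    if "\t" in image_id or "\n" in image_id or "\r" in image_id:
        raise ValueError(f"image id {image_id!r} may not contain tabs or newlines")
    if not image_id:
        raise ValueError("image id may not be empty")
    payload = code.packed().tobytes().hex().upper()
    return f"{image_id}\t{len(code)}\t{payload}"


def parse_code_line(line: str) -> tuple[str, VeinCode]:
    try:
        image_id, length_s, payload = line.rstrip("\n").split("\t")
        length = int(length_s)
        raw = np.frombuffer(bytes.fromhex(payload), dtype=np.uint8)
    except ValueError as exc:
        raise CodeFormatError(f"malformed code record: {line!r}") from exc
    if not length <= raw.size * 8 < length + 8:
        raise CodeFormatError(f"payload of {raw.size * 8} bits does not fit L={length}")
    code = VeinCode.from_packed(raw, length)
    if np.unpackbits(raw)[length:].any():
        raise CodeFormatError("nonzero padding bits in payload")
    return image_id, code


def header_line(spec: BlockSpec) -> str:
    return f"#veincode {FORMAT_VERSION} block={spec} neighbors={NEIGHBOR_CONVENTION}"


def parse_header(line: str) -> BlockSpec:
    fields = line.strip().split()
    if len(fields) != 4 or fields[0] != "#veincode":
        raise CodeFormatError(f"not a veincode header: {line!r}")
    if fields[1] != FORMAT_VERSION:
        raise CodeFormatError(f"unsupported format version {fields[1]!r}")
    kv = dict(f.split("=", 1) for f in fields[2:])
    if kv.get("neighbors") != NEIGHBOR_CONVENTION:
        raise CodeFormatError(
            f"incompatible neighbour convention {kv.get('neighbors')!r} "
            f"(this build uses {NEIGHBOR_CONVENTION})"
        )
    return BlockSpec.parse(kv["block"])


def write_codes(path, records: Iterable[tuple[str, VeinCode]], spec: BlockSpec) -> None:
    with open(path, "w") as fh:
        fh.write(header_line(spec) + "\n")
        for image_id, code in records:
            fh.write(serialize_code(code, image_id) + "\n")


def read_codes(path) -> tuple[BlockSpec, list[tuple[str, VeinCode]]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise CodeFormatError(f"empty code file: {path}")
    spec = parse_header(lines[0])
    return spec, [parse_code_line(line) for line in lines[1:] if line.strip()]


def write_scores_csv(path, rows: Sequence[tuple[str, str, float, bool]]) -> None:
    """Score table: ``probe_id,subject_id,score,decision`` per row."""
    with open(path, "w") as fh:
        fh.write("probe_id,subject_id,score,decision\n")
        for probe_id, subject_id, score, accept in rows:
            fh.write(f"{probe_id},{subject_id},{score:.6f},{'accept' if accept else 'reject'}\n")
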