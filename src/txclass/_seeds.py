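"""Deterministic seed derivation.

A single master seed fans out to every stage through a stage-name-keyed
hash, so any subset of the pipeline can be re-run reproducibly on its own.
"""

from __future__ import annotations

import zlib

_MOD = 2**31 - 1


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed from ``master`` and a sequence of string/int tags.

    The result is a stable function of its inputs, independent of Python's
    per-process hash randomization, and always in ``[0, 2**31)``.
    """
    key = "|".join(str(t) for t in tags).encode()
    return (int(master) * 2654435761 + zlib.crc32(key)) % _MOD
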