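"""Deterministic seed derivation.

Every source of randomness in the package draws from a stream derived from a
single base seed plus a string/int context path, so replicate streams are
independent yet reproducible across processes and Python sessions (unlike the
builtin ``hash``, which is salted per interpreter).
"""

from __future__ import annotations

import hashlib


def derive_seed(*parts: object) -> int:
    """Map an arbitrary context path to a stable 31-bit seed.

    Parameters are combined positionally; ``derive_seed(1, "a")`` and
    ``derive_seed("a", 1)`` differ.
    """
    token = "\x1f".join(repr(p) for p in parts).encode()
    digest = hashlib.blake2b(token, digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
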