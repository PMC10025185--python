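"""CAS Registry Number validation.

A CAS-RN has the form ``NNNNNNN-NN-R``: two to seven digits, a hyphen,
two digits, a hyphen and a single check digit.  The check digit is the
weighted sum of all preceding digits (rightmost weight 1, increasing
leftward) modulo 10.  CAS-RNs are the primary key of the substance
registry, so malformed or mistyped identifiers are rejected at the door
rather than silently propagated.
"""

from __future__ import annotations

import re
from typing import Literal

CasVerdict = Literal["valid", "malformed", "checksum_fail"]

VALID: CasVerdict = "valid"
MALFORMED: CasVerdict = "malformed"
CHECKSUM_FAIL: CasVerdict = "checksum_fail"

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def cas_check_digit(body: str) -> int:
    """Check digit for the digit string preceding the final hyphen.

    ``body`` is the concatenation of the first two segments, e.g.
    ``"10736"`` for 107-36-8.
    """
    total = sum(weight * int(d) for weight, d in enumerate(reversed(body), start=1))
    return total % 10


def validate_cas(cas: str) -> CasVerdict:
    """Classify ``cas`` as ``valid``, ``malformed`` or ``checksum_fail``.

    Total function: any input (including non-string garbage coerced to
    text upstream) yields a verdict, never an exception.
    """
    if not isinstance(cas, str):
        return MALFORMED
    m = _CAS_RE.match(cas.strip())
    if m is None:
        return MALFORMED
    body = m.group(1) + m.group(2)
    if cas_check_digit(body) != int(m.group(3)):
        return CHECKSUM_FAIL
    return VALID


def format_cas(serial: int) -> str:
    """Build a checksum-correct CAS-RN from a positive serial number.

    Used by the synthetic-registry generator: the serial supplies the
    first seven digits (split 5+2) and the check digit is computed.
    """
    if serial < 0:
        raise ValueError("serial must be non-negative")
    body = f"{serial:07d}"
    if len(body) > 9:
        raise ValueError("serial too large for a CAS-RN")
    first, second = body[:-2], body[-2:]
    first = first.lstrip("0") or "10"  # first segment needs >= 2 digits
    if len(first) < 2:
        first = "1" + first
    return f"{first}-{second}-{cas_check_digit(first + second)}"
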