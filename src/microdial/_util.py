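"""Small shared helpers."""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonicalize a free-text drug/region/transmitter name.

    Trims, collapses internal whitespace and case-folds, so that
    "Nucleus  Accumbens " and "nucleus accumbens" compare equal.
    """
    return _WS.sub(" ", str(name).strip()).casefold()
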