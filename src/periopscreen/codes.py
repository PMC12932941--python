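"""ICD-10 code normalization and code-set matching.

Eligibility criteria are defined over *code sets*: small lists of tokens in
three styles commonly seen in computable-phenotype definitions:

* a bare root (``"J40"``) — matches the code itself and every descendant
  (any code that extends the root, e.g. ``J40`` covers ``J40`` only because
  no sub-codes exist, while ``J45`` covers ``J45.20`` etc.);
* an inclusive range (``"J41-J41.8"``) — both endpoints must share the same
  3-character category; membership is decided by lexicographic comparison of
  dot-stripped codes, with descendants of the upper endpoint included
  (``J41.83`` is inside ``J41-J41.8``, ``J41.9`` is not);
* an explicit all-descendants wildcard (``"J09.x"``) — equivalent to the
  bare-root interpretation, kept so resource files can mirror their source
  definition verbatim.

Matching is case-insensitive and deterministic; unparseable tokens fail at
load time (a configuration error), never at match time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import CodeSetError, InvalidCodeError

__all__ = ["normalize_icd", "CodeSet", "code_matches"]

# letter + digit, then alphanumerics; 3-7 chars after dot removal
_CODE_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]{1,5}$")


def normalize_icd(code: str) -> str:
    """Normalize a raw ICD-10 code: strip whitespace, uppercase, drop dots.

    Idempotent. Raises :class:`InvalidCodeError` on empty or garbage input,
    echoing the offending string.
    """
    if not isinstance(code, str) or not code.strip():
        raise InvalidCodeError(f"empty ICD-10 code: {code!r}")
    norm = code.strip().upper().replace(".", "")
    if not _CODE_RE.match(norm):
        raise InvalidCodeError(f"unparseable ICD-10 code: {code!r}")
    return norm


@dataclass(frozen=True)
class _Token:
    kind: str  # "root" | "range"
    raw: str
    root: str = ""
    low: str = ""
    high: str = ""

    def matches(self, norm: str) -> bool:
        if self.kind == "root":
            return norm.startswith(self.root)
        if norm[:3] != self.low[:3]:
            return False
        return self.low <= norm and (norm <= self.high or norm.startswith(self.high))


def _parse_token(raw: str) -> _Token:
    token = raw.strip()
    if not token:
        raise CodeSetError(f"empty code-set token: {raw!r}")
    if "-" in token:
        parts = token.split("-")
        if len(parts) != 2:
            raise CodeSetError(f"malformed range token: {raw!r}")
        try:
            low, high = (normalize_icd(p) for p in parts)
        except InvalidCodeError as exc:
            raise CodeSetError(f"unparseable range token {raw!r}: {exc}") from exc
        if low[:3] != high[:3]:
            raise CodeSetError(
                f"range token {raw!r} spans ICD-10 categories ({low[:3]} vs {high[:3]})"
            )
        if not low <= high:
            raise CodeSetError(f"range token {raw!r} has endpoints out of order")
        return _Token("range", raw=token, low=low, high=high)
    if token.upper().endswith(".X"):
        token = token[:-2]
    try:
        root = normalize_icd(token)
    except InvalidCodeError as exc:
        raise CodeSetError(f"unparseable code-set token {raw!r}: {exc}") from exc
    return _Token("root", raw=raw.strip(), root=root)


@dataclass(frozen=True)
class CodeSet:
    """A named, parsed ICD-10 code set.

    Parameters
    ----------
    name
        Identifier used in criterion evidence strings.
    tokens
        Token strings in any of the three supported styles.
    """

    name: str
    tokens: tuple[str, ...]
    _parsed: tuple[_Token, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if isinstance(self.tokens, (list, set)):
            object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "_parsed", tuple(_parse_token(t) for t in self.tokens))

    def matches(self, code: str) -> bool:
        """True iff the (raw) code falls inside this set."""
        norm = normalize_icd(code)
        return any(tok.matches(norm) for tok in self._parsed)


def code_matches(code: str, code_set: CodeSet) -> bool:
    """Functional alias for :meth:`CodeSet.matches`."""
    return code_set.matches(code)
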