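"""PROSITE-style domain-extraction patterns and their matcher.

Two-domain sulfhydryl oxidases (QSOX) are located in protein sequences with
hand-built PROSITE-style patterns, one for the thioredoxin (Trx) oxidoreductase
domain and one for the Erv sulfhydryl-oxidase domain.  A pattern is an ordered
list of elements, each a literal residue, a residue class ``[...]``, or a
wildcard ``x(n)`` / ``x(n,m)``; elements are separated by ``-``.  Named capture
labels mark the element runs holding the redox-active CXXC motifs so that
downstream annotation can read motif coordinates straight off a match.

The matcher is an exact backtracking engine with fully specified tie-breaking
(leftmost start, then minimal span, then earlier expansion of earlier
wildcards), so results are deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Trx-domain extraction pattern.  Captures: ``trx_cxxc`` = the redox-active
#: [CS]-x(2)-[CS] site, ``cx6_8c`` = the structural C-x(5,9)-C disulfide loop.
TRX_PATTERN_TEXT = (
    "X(5)-[DGEILQKVNRM]-x(5)-[WFYKSGT]-[CS]-x(2)-[CS]-x(4)-[PRSDETGAKHN]"
    "-x(10,35)-C-x(5,9)-C-x(8)-P-[AGTSLMFRHKNQ]-X(9)"
)

#: Erv-domain extraction pattern.  Captures: ``erv_cxxc`` = the proximal
#: C-x(2)-[CSG] site, ``ct_cxxc`` = the carboxy-terminal C-x(2)-C motif.
ERV_PATTERN_TEXT = (
    "X(30)-[TNPSLF]-C-[GSTA]-X(18,54)-C-x(2)-[CSG]-x(2)-[HNKEY]-[FIL]"
    "-x(40,116)-[WFY]-x(5)-C-x(2)-C"
)


class PatternParseError(ValueError):
    """Raised for a malformed pattern, naming the offending token."""


@dataclass(frozen=True)
class Element:
    """One pattern element.

    kind is ``literal`` (one residue), ``class`` (a residue set) or ``wild``
    (any residues, span between min_len and max_len inclusive).
    """

    kind: str
    residues: frozenset[str] = frozenset()
    min_len: int = 1
    max_len: int = 1

    @property
    def variable(self) -> bool:
        return self.min_len != self.max_len

    def admits(self, residue: str) -> bool:
        """Whether this element accepts *residue* at a single position.

        The unknown residue 'X' in a sequence satisfies wildcards only,
        never literals or classes.
        """
        if self.kind == "wild":
            return True
        if residue == "X":
            return False
        return residue in self.residues


@dataclass(frozen=True)
class DomainPattern:
    """Compiled pattern: ordered elements plus named capture element-ranges."""

    elements: tuple[Element, ...]
    captures: dict[str, tuple[int, int]] = field(default_factory=dict)  # inclusive
    name: str = ""

    @property
    def min_span(self) -> int:
        return sum(e.min_len for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_len for e in self.elements)

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class PatternMatch:
    """A located pattern occurrence.

    ``boundaries`` holds the absolute start position of every element plus the
    match end (length = n_elements + 1); captured spans are 0-based half-open.
    """

    seqid: str
    start: int
    end: int
    boundaries: tuple[int, ...]
    captured: dict[str, tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _parse_element(token: str) -> Element:
    if not token:
        raise PatternParseError("empty pattern element")
    if token.startswith("["):
        if not token.endswith("]") or len(token) < 3:
            raise PatternParseError(f"malformed residue class {token!r}")
        body = token[1:-1].upper()
        bad = [c for c in body if c not in AMINO_ACIDS]
        if bad:
            raise PatternParseError(f"invalid residue {bad[0]!r} in class {token!r}")
        return Element("class", frozenset(body))
    if token[0] in "Xx":
        if len(token) == 1:
            return Element("wild", min_len=1, max_len=1)
        if not (token.endswith(")") and token[1] == "("):
            raise PatternParseError(f"malformed wildcard {token!r}")
        body = token[2:-1]
        parts = body.split(",")
        try:
            nums = [int(p) for p in parts]
        except ValueError:
            raise PatternParseError(f"malformed wildcard count in {token!r}") from None
        if len(nums) == 1:
            lo = hi = nums[0]
        elif len(nums) == 2:
            lo, hi = nums
        else:
            raise PatternParseError(f"malformed wildcard {token!r}")
        if lo < 0 or lo > hi:
            raise PatternParseError(f"invalid wildcard bounds in {token!r}")
        return Element("wild", min_len=lo, max_len=hi)
    if len(token) == 1 and token.upper() in AMINO_ACIDS:
        return Element("literal", frozenset(token.upper()))
    raise PatternParseError(f"malformed pattern element {token!r}")


def parse_pattern(text: str, name: str = "",
                  captures: dict[str, tuple[int, int]] | None = None) -> DomainPattern:
    """Parse a PROSITE-style pattern string into a :class:`DomainPattern`.

    Elements are '-'-separated; ``X``/``x`` are equivalent; forms are a single
    residue letter, ``[CLASS]``, ``X(n)`` and ``X(n,m)``.  *captures* maps a
    label to an inclusive (first_element, last_element) index range.
    """
    elements = tuple(_parse_element(tok) for tok in text.strip().split("-"))
    caps = dict(captures or {})
    for label, (i, j) in caps.items():
        if not (0 <= i <= j < len(elements)):
            raise PatternParseError(f"capture {label!r} range {(i, j)} out of bounds")
    return DomainPattern(elements, caps, name=name)


def trx_pattern() -> DomainPattern:
    """The built-in Trx-domain pattern with its motif captures."""
    return parse_pattern(
        TRX_PATTERN_TEXT, name="trx",
        captures={"trx_cxxc": (4, 6), "cx6_8c": (10, 12)},
    )


def erv_pattern() -> DomainPattern:
    """The built-in Erv-domain pattern with its motif captures."""
    return parse_pattern(
        ERV_PATTERN_TEXT, name="erv",
        captures={"erv_cxxc": (5, 7), "ct_cxxc": (14, 16)},
    )


def _match_from(pattern: DomainPattern, seq: str, start: int,
                rest_min: list[int]):
    """DFS over element expansions from *start*, yielding boundary tuples.

    Wildcard lengths are tried shortest-first, so paths come out in
    lexicographic order of the expansion vector.
    """
    n = len(seq)
    elements = pattern.elements

    def dfs(idx: int, pos: int, bounds: list[int]):
        if idx == len(elements):
            yield tuple(bounds)
            return
        # prune: remaining elements must fit
        if pos + rest_min[idx] > n:
            return
        e = elements[idx]
        if e.kind == "wild":
            hi = min(e.max_len, n - pos - rest_min[idx + 1])
            for length in range(e.min_len, hi + 1):
                bounds.append(pos + length)
                yield from dfs(idx + 1, pos + length, bounds)
                bounds.pop()
        else:
            if pos < n and e.admits(seq[pos]):
                bounds.append(pos + 1)
                yield from dfs(idx + 1, pos + 1, bounds)
                bounds.pop()

    yield from dfs(0, start, [start])


def _resolve_captures(pattern: DomainPattern,
                      boundaries: tuple[int, ...]) -> dict[str, tuple[int, int]]:
    return {label: (boundaries[i], boundaries[j + 1])
            for label, (i, j) in pattern.captures.items()}


def scan(pattern: DomainPattern, sequence: str, mode: str = "first",
         seqid: str = "") -> list[PatternMatch]:
    """Locate pattern occurrences in *sequence*.

    mode='first' returns the leftmost match (ties: minimal total span, then
    earlier expansion of earlier wildcards); mode='all' returns one match per
    distinct (start, end) span, each with its lexicographically earliest
    expansion.  An empty list is a valid outcome.
    """
    if mode not in ("first", "all"):
        raise ValueError(f"unknown scan mode {mode!r}")
    seq = sequence.upper()
    n = len(seq)
    elements = pattern.elements
    # suffix min/max span sums for pruning
    rest_min = [0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        rest_min[i] = rest_min[i + 1] + elements[i].min_len

    out: list[PatternMatch] = []
    for start in range(0, n - pattern.min_span + 1):
        seen_ends: set[int] = set()
        at_start: list[PatternMatch] = []
        for bounds in _match_from(pattern, seq, start, rest_min):
            end = bounds[-1]
            if end in seen_ends:
                continue
            seen_ends.add(end)
            at_start.append(PatternMatch(seqid, start, end, bounds,
                                         _resolve_captures(pattern, bounds)))
        if mode == "first" and at_start:
            # shortest-first expansion order does not enumerate ends in
            # ascending order, so pick the minimal span here; the expansion
            # kept per end is already the lexicographically earliest one.
            return [min(at_start, key=lambda m: m.end)]
        out.extend(at_start)
    return out


def matches_to_tsv(matches: list[PatternMatch], path,
                   pattern_name: str = "") -> None:
    """Write matches and their captures as TSV (0-based half-open spans)."""
    with open(path, "w") as fh:
        fh.write("seqid\tpattern\tstart\tend\tcapture\tcapture_start"
                 "\tcapture_end\n")
        for m in matches:
            fh.write(f"{m.seqid}\t{pattern_name}\t{m.start}\t{m.end}\t.\t.\t.\n")
            for lab, (s, e) in sorted(m.captured.items()):
                fh.write(f"{m.seqid}\t{pattern_name}\t{m.start}\t{m.end}"
                         f"\t{lab}\t{s}\t{e}\n")
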