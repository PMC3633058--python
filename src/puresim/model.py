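"""Parser and serializer for the plain-text reaction-model dialect.

The dialect mirrors standard biochemical notation, one statement per line:

    # comment (anywhere; trailing comments allowed)
    init GTP 120000                  # initial copy number
    0.9, null > A                    # zero-order kinetic reaction
    1000000, T7ELGT4 + GTP > T7pregEL4
    -, 20 gtr4 + 20 atr4 + T7ELGT4 + DNA5 > T7ELGT5 + RNA4 + DNA3
    @ 10800 rate rib_inact 0.0005    # timed control actions
    @ 10 add 100 A
    @ 20 remove 5 A

A kinetic line is ``<rate>, <lhs> > <rhs>``; the hyphen in place of a rate
constant marks an *immediate* reaction, which fires as soon as the
left-hand stoichiometry is satisfied.  Terms are ``+``-separated with an
optional integer coefficient prefix ("20 gtr4"); ``null`` denotes an empty
side.  Reaction lines may carry an explicit label (``myid: 0.9, null > A``);
unlabeled reactions get positional ids R1, R2, ... / I1, I2, ...
Declaration order of immediates is preserved: it is the tie-break order of
the simulator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .ssa import ImmediateReaction, KineticReaction, TimedEvent

__all__ = [
    "ModelDocument",
    "Diagnostic",
    "ParseError",
    "parse_model",
    "serialize_model",
    "validate_model",
    "load_model",
    "save_model",
]


class ParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Diagnostic:
    level: str  # "warning" | "error"
    message: str
    line: int | None = None

    def __str__(self):
        where = f" (line {self.line})" if self.line is not None else ""
        return f"{self.level}: {self.message}{where}"


@dataclass
class ModelDocument:
    """Structured model: initial counts, reactions, immediates, timed events.

    Species referenced but never declared with ``init`` are added with
    count 0 and listed in ``implicit_species`` (validate_model warns about
    them).
    """

    initial_counts: dict[str, int] = field(default_factory=dict)
    kinetic_reactions: list[KineticReaction] = field(default_factory=list)
    immediate_reactions: list[ImmediateReaction] = field(default_factory=list)
    timed_events: list[TimedEvent] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)
    implicit_species: list[str] = field(default_factory=list, compare=False)

    @property
    def species(self) -> list[str]:
        return list(self.initial_counts.keys())

    def reaction(self, rid: str) -> KineticReaction:
        for r in self.kinetic_reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_ID_RE = re.compile(_IDENT + r"\Z")
_TERM_RE = re.compile(rf"(?:(\d+)\s+)?({_IDENT})\Z")
_NUMBER_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?\Z")


def _parse_side(text: str, lineno: int) -> list[tuple[str, int]]:
    text = text.strip()
    if text == "null" or text == "":
        return []
    pairs: list[tuple[str, int]] = []
    for raw in text.split("+"):
        term = raw.strip()
        m = _TERM_RE.match(term)
        if not m or m.group(2) == "null":
            raise ParseError(f"malformed term {term!r}", lineno)
        coef = int(m.group(1)) if m.group(1) else 1
        if coef <= 0:
            raise ParseError(f"non-positive coefficient in {term!r}", lineno)
        pairs.append((m.group(2), coef))
    return pairs


def parse_model(text: str) -> ModelDocument:
    """Parse model text into a ModelDocument; line numbers are retained on
    reactions and events for diagnostics."""
    doc = ModelDocument()
    auto_k = auto_i = 0
    seen_ids: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw
        if "#" in line:
            comment = line[line.index("#"):].lstrip("#").strip()
            line = line[: line.index("#")]
            if comment:
                doc.comments.append(comment)
        line = line.strip()
        if not line:
            continue

        if line.startswith("@"):
            doc.timed_events.append(_parse_event(line, lineno))
            continue

        if line.startswith("init "):
            parts = line.split()
            if len(parts) != 3:
                raise ParseError("expected 'init <species> <count>'", lineno)
            _, name, count = parts
            if not _ID_RE.match(name) or name == "null":
                raise ParseError(f"invalid species name {name!r}", lineno)
            if name in doc.initial_counts and name not in doc.implicit_species:
                raise ParseError(f"duplicate species declaration {name!r}", lineno)
            try:
                n = int(count)
            except ValueError:
                raise ParseError(f"invalid count {count!r}", lineno) from None
            if n < 0:
                raise ParseError(f"negative initial count for {name!r}", lineno)
            if name in doc.implicit_species:
                doc.implicit_species.remove(name)
            doc.initial_counts[name] = n
            continue

        # reaction line, optionally labeled "<id>: ..."
        label = None
        m = re.match(rf"({_IDENT})\s*:\s*(.*)\Z", line)
        if m and "," in m.group(2):
            label, line = m.group(1), m.group(2)
        if "," not in line:
            raise ParseError("expected '<rate>, <reactants> > <products>'", lineno)
        rate_part, _, body = line.partition(",")
        rate_part = rate_part.strip()
        if ">" not in body:
            raise ParseError("missing '>' between reactants and products", lineno)
        lhs, _, rhs = body.partition(">")
        reactants = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)

        if rate_part == "-":
            if not reactants:
                raise ParseError("immediate reaction with empty trigger", lineno)
            auto_i += 1
            rid = label or f"I{auto_i}"
            if rid in seen_ids:
                raise ParseError(f"duplicate reaction id {rid!r}", lineno)
            seen_ids.add(rid)
            doc.immediate_reactions.append(
                ImmediateReaction(id=rid, trigger=reactants, products=products, line=lineno)
            )
        else:
            if not _NUMBER_RE.match(rate_part):
                raise ParseError(f"invalid rate constant {rate_part!r}", lineno)
            rate = float(rate_part)
            if rate < 0:
                raise ParseError(f"negative rate constant {rate}", lineno)
            auto_k += 1
            rid = label or f"R{auto_k}"
            if rid in seen_ids:
                raise ParseError(f"duplicate reaction id {rid!r}", lineno)
            seen_ids.add(rid)
            doc.kinetic_reactions.append(
                KineticReaction(id=rid, c=rate, reactants=reactants, products=products,
                                line=lineno)
            )

        for name, _nu in reactants + products:
            if name not in doc.initial_counts:
                doc.initial_counts[name] = 0
                doc.implicit_species.append(name)

    for e in doc.timed_events:
        if e.kind in ("add", "remove") and e.species not in doc.initial_counts:
            doc.initial_counts[e.species] = 0
            doc.implicit_species.append(e.species)
    doc.timed_events.sort(key=lambda e: e.time)
    return doc


def _parse_event(line: str, lineno: int) -> TimedEvent:
    parts = line[1:].split()
    if len(parts) != 4:
        raise ParseError(
            "expected '@ <time> add|remove <count> <species>' or "
            "'@ <time> rate <reaction-id> <value>'", lineno)
    t_str, kind, arg1, arg2 = parts
    try:
        t = float(t_str)
    except ValueError:
        raise ParseError(f"invalid event time {t_str!r}", lineno) from None
    if t < 0:
        raise ParseError("negative event time", lineno)
    if kind in ("add", "remove"):
        try:
            amount = int(arg1)
        except ValueError:
            raise ParseError(f"invalid amount {arg1!r}", lineno) from None
        if amount <= 0:
            raise ParseError("event amount must be a positive integer", lineno)
        if not _ID_RE.match(arg2):
            raise ParseError(f"invalid species name {arg2!r}", lineno)
        return TimedEvent(time=t, kind=kind, species=arg2, amount=amount, line=lineno)
    if kind == "rate":
        try:
            value = float(arg2)
        except ValueError:
            raise ParseError(f"invalid rate value {arg2!r}", lineno) from None
        if value < 0:
            raise ParseError("negative rate value", lineno)
        return TimedEvent(time=t, kind="rate", reaction_id=arg1, value=value, line=lineno)
    raise ParseError(f"unknown event kind {kind!r}", lineno)


def _fmt_side(pairs: list[tuple[str, int]]) -> str:
    if not pairs:
        return "null"
    return " + ".join(f"{nu} {name}" if nu != 1 else name for name, nu in pairs)


def _fmt_rate(c: float) -> str:
    # shortest representation that round-trips through float()
    return repr(c) if c != int(c) else str(int(c))


def serialize_model(doc: ModelDocument) -> str:
    """Emit model text such that parse_model(serialize_model(doc)) is
    structurally equal to doc (round-trip identity)."""
    out: list[str] = []
    for comment in doc.comments:
        out.append(f"# {comment}")
    for name, n in doc.initial_counts.items():
        if name in doc.implicit_species:
            continue
        out.append(f"init {name} {n}")
    for r in doc.kinetic_reactions:
        out.append(f"{r.id}: {_fmt_rate(r.c)}, {_fmt_side(r.reactants)} > {_fmt_side(r.products)}")
    for im in doc.immediate_reactions:
        out.append(f"{im.id}: -, {_fmt_side(im.trigger)} > {_fmt_side(im.products)}")
    for e in sorted(doc.timed_events, key=lambda e: e.time):
        if e.kind == "rate":
            out.append(f"@ {e.time!r} rate {e.reaction_id} {e.value!r}")
        else:
            out.append(f"@ {e.time!r} {e.kind} {e.amount} {e.species}")
    return "\n".join(out) + ("\n" if out else "")


def validate_model(doc: ModelDocument) -> list[Diagnostic]:
    """Static checks; returns diagnostics, never raises.

    Reports implicitly-declared species, consumable species that can never
    be present (never produced, zero initial count, yet consumed), and
    immediates whose products fully replenish their own trigger (infinite
    cascade).
    """
    diags: list[Diagnostic] = []
    produced: set[str] = set()
    consumed: dict[str, int | None] = {}
    for r in doc.kinetic_reactions:
        produced.update(name for name, _ in r.products)
        for name, _ in r.reactants:
            consumed.setdefault(name, r.line)
    for im in doc.immediate_reactions:
        produced.update(name for name, _ in im.products)
        for name, _ in im.trigger:
            consumed.setdefault(name, im.line)
    for e in doc.timed_events:
        if e.kind == "add":
            produced.add(e.species)

    implicit_lines = {}
    for r in doc.kinetic_reactions:
        for name, _ in r.reactants + r.products:
            implicit_lines.setdefault(name, r.line)
    for im in doc.immediate_reactions:
        for name, _ in im.trigger + im.products:
            implicit_lines.setdefault(name, im.line)
    for name in doc.implicit_species:
        diags.append(Diagnostic(
            "warning",
            f"species {name!r} used but never declared with 'init'; assuming 0",
            implicit_lines.get(name),
        ))

    for name, line in consumed.items():
        if doc.initial_counts.get(name, 0) == 0 and name not in produced:
            diags.append(Diagnostic(
                "warning",
                f"species {name!r} is consumed but never produced and starts at 0 "
                "(dead reaction path)",
                line,
            ))

    for im in doc.immediate_reactions:
        prod = {name: nu for name, nu in im.products}
        if all(prod.get(name, 0) >= nu for name, nu in im.trigger):
            diags.append(Diagnostic(
                "warning",
                f"immediate {im.id!r} replenishes its own trigger (self-triggering "
                "cascade would never reach quiescence)",
                im.line,
            ))
    return diags


def load_model(path) -> ModelDocument:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def save_model(doc: ModelDocument, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_model(doc))
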