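"""Plain-text rules format for Boolean networks (BoolNet-style).

One dialect, two line forms:

* Expression lines: ``target, expression`` with operators ``!`` (NOT),
  ``&`` (AND), ``|`` (OR), parentheses, and the constants ``0``/``1``.
  The input set of the target is exactly the set of variables appearing in
  the expression.  A ``targets, factors`` header line is accepted and
  ignored, as are blank lines and ``#`` comments.

* Table lines: ``table target, input1 input2 ..., k0 k1 k2 k3`` listing the
  output vector explicitly in the canonical input-subset enumeration order
  (∅ first, then singletons, then pairs, each level lexicographic).  This
  form is required for probabilistic likelihood vectors and for rules whose
  truth table ignores all of its declared inputs.

Variable declaration order is the order of rule lines; every variable that is
referenced must also be declared as a target somewhere in the file.

Per-variable rates travel separately as a two-column TSV (variable, rate).
"""

from __future__ import annotations

import re
from pathlib import Path

from .network import DETERMINISTIC, PROBABILISTIC, BooleanNetwork, RateVector, UpdateSpec
from .subsets import canonical_order, members


class ParseError(ValueError):
    """A rules file could not be parsed; the message names the offending line."""


_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][\w.]*)|(?P<const>[01])|(?P<op>[!&|()]))")


def _tokenize(expr: str, lineno: int) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m or m.end() == pos:
            if expr[pos:].strip():
                raise ParseError(f"line {lineno}: cannot tokenize {expr[pos:].strip()!r}")
            break
        if m.group("name"):
            tokens.append(("name", m.group("name")))
        elif m.group("const"):
            tokens.append(("const", m.group("const")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive-descent parser: OR < AND < NOT < atom."""

    def __init__(self, tokens, lineno):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.pos != len(self.tokens):
            raise ParseError(f"line {self.lineno}: trailing tokens after expression")
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == ("op", "|"):
            self.take()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() == ("op", "&"):
            self.take()
            node = ("and", node, self.parse_not())
        return node

    def parse_not(self):
        if self.peek() == ("op", "!"):
            self.take()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self):
        kind, val = self.take()
        if kind == "name":
            return ("var", val)
        if kind == "const":
            return ("const", int(val))
        if (kind, val) == ("op", "("):
            node = self.parse_or()
            if self.take() != ("op", ")"):
                raise ParseError(f"line {self.lineno}: unbalanced parentheses")
            return node
        raise ParseError(f"line {self.lineno}: unexpected token {val!r}")


def _expr_vars(node, acc: list[str]):
    tag = node[0]
    if tag == "var":
        if node[1] not in acc:
            acc.append(node[1])
    elif tag == "not":
        _expr_vars(node[1], acc)
    elif tag in ("and", "or"):
        _expr_vars(node[1], acc)
        _expr_vars(node[2], acc)


def _expr_eval(node, on: set[str]) -> bool:
    tag = node[0]
    if tag == "var":
        return node[1] in on
    if tag == "const":
        return bool(node[1])
    if tag == "not":
        return not _expr_eval(node[1], on)
    if tag == "and":
        return _expr_eval(node[1], on) and _expr_eval(node[2], on)
    return _expr_eval(node[1], on) or _expr_eval(node[2], on)


def parse_network(text: str) -> BooleanNetwork:
    """Parse the rules dialect into a :class:`BooleanNetwork`."""
    targets: list[str] = []
    bodies: list[tuple[int, str, object]] = []  # (lineno, form, payload)
    seen: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if re.fullmatch(r"targets\s*,\s*factors", line, flags=re.IGNORECASE):
            continue
        if line.lower().startswith("table "):
            fields = [f.strip() for f in line[6:].split(",")]
            if len(fields) != 3:
                raise ParseError(
                    f"line {lineno}: table form is 'table target, inputs, k values'"
                )
            target, inputs_field, k_field = fields
            inputs = inputs_field.split()
            try:
                k = tuple(_number(v) for v in k_field.split())
            except ValueError:
                raise ParseError(f"line {lineno}: bad k value in {k_field!r}") from None
            payload: object = (inputs, k)
            form = "table"
        else:
            if "," not in line:
                raise ParseError(f"line {lineno}: expected 'target, expression'")
            target, expr = (f.strip() for f in line.split(",", 1))
            payload = _ExprParser(_tokenize(expr, lineno), lineno).parse()
            form = "expr"
        if not re.fullmatch(r"[A-Za-z_][\w.]*", target):
            raise ParseError(f"line {lineno}: invalid target name {target!r}")
        if target in seen:
            raise ParseError(f"line {lineno}: duplicate target {target!r}")
        seen.add(target)
        targets.append(target)
        bodies.append((lineno, form, payload))

    if not targets:
        raise ParseError("no rules found")
    index = {name: i for i, name in enumerate(targets)}

    rules: list[UpdateSpec] = []
    probabilistic = False
    for i, (lineno, form, payload) in enumerate(bodies):
        if form == "table":
            input_names, k = payload
            try:
                inputs = tuple(sorted(index[nm] for nm in input_names))
            except KeyError as exc:
                raise ParseError(f"line {lineno}: undeclared variable {exc.args[0]!r}") from None
            if len(set(inputs)) != len(inputs):
                raise ParseError(f"line {lineno}: repeated input variable")
            if len(k) != 1 << len(inputs):
                raise ParseError(
                    f"line {lineno}: {len(k)} k values for {len(inputs)} inputs "
                    f"(expected {1 << len(inputs)})"
                )
            # Table columns are given in the canonical order of the *listed*
            # input order sorted by index, which is how we stored them.
            if any(not 0 <= v <= 1 for v in k):
                raise ParseError(f"line {lineno}: k values must lie in [0, 1]")
            if any(v not in (0, 1) for v in k):
                probabilistic = True
        else:
            node = payload
            used: list[str] = []
            _expr_vars(node, used)
            for nm in used:
                if nm not in index:
                    raise ParseError(f"line {lineno}: undeclared variable {nm!r}")
            inputs = tuple(sorted(index[nm] for nm in used))
            input_names_sorted = [targets[j] for j in inputs]
            k = tuple(
                int(_expr_eval(node, {input_names_sorted[j] for j in members(rho)}))
                for rho in canonical_order(len(inputs))
            )
        rules.append(UpdateSpec(i, inputs, k))

    kind = PROBABILISTIC if probabilistic else DETERMINISTIC
    return BooleanNetwork(tuple(targets), tuple(rules), kind)


def _number(text: str):
    if re.fullmatch(r"[01]", text):
        return int(text)
    return float(text)


def serialize_network(net: BooleanNetwork) -> str:
    """Render a network in the rules dialect; ``parse_network`` round-trips it.

    Deterministic non-constant rules are written as a disjunctive normal form
    over all inputs (so the reparsed input set is identical); constant-output
    rules with declared inputs and probabilistic rules use the table form.
    """
    lines = ["targets, factors"]
    for i, rule in enumerate(net.rules):
        name = net.names[i]
        input_names = [net.names[j] for j in rule.inputs]
        if rule.deterministic and not rule.inputs:
            lines.append(f"{name}, {int(rule.k[0])}")
            continue
        if rule.deterministic and 0 < sum(rule.k) < len(rule.k):
            terms = []
            for pos, rho in enumerate(canonical_order(len(rule.inputs))):
                if not rule.k[pos]:
                    continue
                on = set(members(rho))
                lits = [
                    nm if j in on else f"!{nm}"
                    for j, nm in enumerate(input_names)
                ]
                terms.append("(" + " & ".join(lits) + ")")
            lines.append(f"{name}, " + " | ".join(terms))
        else:
            kvals = " ".join(_format_k(v) for v in rule.k)
            lines.append(f"table {name}, {' '.join(input_names)}, {kvals}")
    return "\n".join(lines) + "\n"


def _format_k(v) -> str:
    if v in (0, 1):
        return str(int(v))
    return f"{float(v):.17g}"


def load_network(path) -> BooleanNetwork:
    return parse_network(Path(path).read_text())


def save_network(net: BooleanNetwork, path) -> None:
    Path(path).write_text(serialize_network(net))


def load_rates(path, net: BooleanNetwork) -> RateVector:
    """Read a two-column TSV (variable, rate) into a per-variable rate vector.

    Variables missing from the file default to rate 1 (deterministic limit).
    """
    rates: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"rates line {lineno}: expected 'variable<TAB>rate'")
        name, value = parts
        if name in ("variable", "rate"):
            continue
        net.index(name)  # raises KeyError for unknown names
        rates[name] = float(value)
    return RateVector.for_network(net, rates)
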