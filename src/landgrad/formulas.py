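"""Term language and design matrices for the occupancy submodels.

A tiny R-style formula grammar covers every structure used in the
candidate sets:

* ``1`` — intercept only;
* main effects: ``city`` (factor), ``date``, ``date2`` (the squared
  date, computed at design time), ``HS``, ``BG`` or any numeric site
  covariate;
* ``a:b`` — interaction without main effects;
* ``a*b`` — crossing, expands to ``a + b + a:b``;
* parenthesized crossing: ``city*(HS+BG)`` -> mains plus ``city:HS``
  and ``city:BG``; ``city*(HS*BG)`` -> all mains, ``HS:BG``, both
  city two-ways, and the three-way.

Coding is treatment contrasts with the alphabetically first factor
level as reference and a single intercept per submodel, so a factor
with L levels contributes L-1 columns and an interaction contributes
the product of its components' column counts. Under marginality
(default) ``date2`` requires ``date`` and interaction terms require
their main effects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["parse_formula", "TermList", "DesignInfo", "build_design", "count_columns"]

_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|\d+|[()*:+])")


def _tokenize(formula: str) -> list[str]:
    out, pos = [], 0
    s = formula.strip()
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m:
            raise ValueError(f"cannot parse formula at: {s[pos:]!r}")
        out.append(m.group(1))
        pos = m.end()
    return out


class _Parser:
    """Recursive descent over  expr := cross (+ cross)* ;
    cross := atom ((*|:) atom)* ; atom := name | '1' | '(' expr ')'.

    Terms are tuples of variable names; () denotes the intercept.
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def eat(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expr(self) -> list[tuple]:
        terms = self.cross()
        while self.peek() == "+":
            self.eat()
            terms = _union(terms, self.cross())
        return terms

    def cross(self) -> list[tuple]:
        terms = self.atom()
        while self.peek() in ("*", ":"):
            op = self.eat()
            rhs = self.atom()
            if op == "*":
                prod = [_combine(a, b) for a in terms for b in rhs]
                terms = _union(_union(terms, rhs), prod)
            else:
                terms = [_combine(a, b) for a in terms for b in rhs]
        return terms

    def atom(self) -> list[tuple]:
        tok = self.eat()
        if tok == "(":
            inner = self.expr()
            if self.eat() != ")":
                raise ValueError("unbalanced parentheses in formula")
            return inner
        if tok == "1":
            return [()]
        if tok is None or tok in "()*:+":
            raise ValueError(f"unexpected token {tok!r} in formula")
        return [(tok,)]


def _combine(a: tuple, b: tuple) -> tuple:
    seen = list(a)
    for v in b:
        if v not in seen:
            seen.append(v)
    return tuple(seen)


def _union(a: list, b: list) -> list:
    out = list(a)
    for t in b:
        if t not in out:
            out.append(t)
    return out


@dataclass(frozen=True)
class TermList:
    """Parsed model side: ordered terms, intercept first."""

    formula: str
    terms: tuple

    def variables(self) -> list[str]:
        seen = []
        for t in self.terms:
            for v in t:
                if v not in seen:
                    seen.append(v)
        return seen


def parse_formula(formula: str, marginality: bool = True) -> TermList:
    """Parse a submodel formula into an ordered term list.

    The intercept is always included. With ``marginality`` (default),
    ``date2`` requires ``date`` and every interaction requires its
    main effects.
    """
    tokens = _tokenize(formula)
    parser = _Parser(tokens)
    terms = parser.expr()
    if parser.peek() is not None:
        raise ValueError(f"trailing tokens in formula {formula!r}")
    # intercept first, then mains/interactions in appearance order
    ordered = [()] + [t for t in terms if t != ()]
    if marginality:
        flat = set(ordered)
        for t in ordered:
            if len(t) > 1:
                for v in t:
                    if (v,) not in flat:
                        raise ValueError(
                            f"interaction {':'.join(t)} lacks main effect {v} "
                            "(marginality violated)"
                        )
        if any("date2" in t for t in ordered) and ("date",) not in flat:
            raise ValueError("date2 requires the linear date term (marginality)")
    return TermList(formula, tuple(ordered))


@dataclass
class DesignInfo:
    """Frozen coding information for one submodel design.

    Stores factor levels observed at fit time so prediction data is
    coded identically; unknown levels at prediction raise.
    """

    termlist: TermList
    factor_levels: dict = field(default_factory=dict)
    column_names: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)


def _base_columns(var: str, frame: pd.DataFrame, levels: dict):
    """Coded columns for one elementary variable."""
    if var == "date2":
        if "date" not in frame.columns:
            raise ValueError("design needs a 'date' column for date2")
        return [("date2", frame["date"].to_numpy(dtype=float) ** 2)]
    if var not in frame.columns:
        raise ValueError(f"covariate {var!r} missing from data")
    col = frame[var]
    if var in levels or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        if var not in levels:
            levels[var] = sorted(map(str, col.unique()))
        lev = levels[var]
        vals = col.astype(str)
        unknown = set(vals.unique()) - set(lev)
        if unknown:
            raise ValueError(f"unknown {var} level(s): {sorted(unknown)}")
        return [
            (f"{var}[{l}]", (vals == l).to_numpy(dtype=float)) for l in lev[1:]
        ]
    return [(var, col.to_numpy(dtype=float))]


def build_design(
    termlist: TermList,
    frame: pd.DataFrame,
    info: DesignInfo | None = None,
    factor_vars: tuple = ("city",),
) -> tuple[np.ndarray, DesignInfo]:
    """Materialize the design matrix for a data frame.

    When ``info`` is given (from a previous fit) its factor levels are
    reused, which is how prediction rows are coded consistently.
    """
    levels = dict(info.factor_levels) if info is not None else {}
    if info is None:
        for var in termlist.variables():
            if var in factor_vars and var in frame.columns:
                levels[var] = sorted(map(str, frame[var].unique()))
    names, cols = [], []
    for term in termlist.terms:
        if term == ():
            names.append("(Intercept)")
            cols.append(np.ones(len(frame)))
            continue
        parts = [_base_columns(v, frame, levels) for v in term]
        combos = [([], np.ones(len(frame)))]
        for part in parts:
            combos = [
                (labels + [nm], vals * arr) for labels, vals in combos for nm, arr in part
            ]
        for labels, vals in combos:
            names.append(":".join(labels))
            cols.append(vals)
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    out_info = DesignInfo(termlist, levels, names)
    if info is not None and info.column_names and names != info.column_names:
        raise ValueError("design columns differ from fitted design")
    return X, out_info


def count_columns(termlist: TermList, n_levels: dict) -> int:
    """Design width without data: factors contribute L-1 per appearance.

    ``n_levels`` maps factor name -> number of levels; all other
    variables are continuous (one column).
    """
    total = 0
    for term in termlist.terms:
        width = 1
        for v in term:
            width *= (n_levels[v] - 1) if v in n_levels else 1
        total += width
    return total
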