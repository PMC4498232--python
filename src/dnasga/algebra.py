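"""Exact arithmetic for quaternary cyclic codes.

This module provides the algebra underneath single-error-correcting BCH
codes on DNA alphabets:

* ``GF(4)`` — the four-element field ``{0, 1, a, b}`` with ``b = a + 1``
  and ``a^2 = a + 1`` (arithmetic modulo ``x^2 + x + 1`` over GF(2)).
  Elements are carried as the integers ``0, 1, 2, 3`` with ``2 = a`` and
  ``3 = b``; addition is XOR.
* ``GF(4^m)`` — the field extension generated by a primitive polynomial
  over GF(4) (:class:`FieldContext`), with a primitive element ``alpha``
  of multiplicative order ``4^m - 1``.
* ``Z4[x]`` and the Galois ring ``GR(4, m) = Z4[x]/(h(x))`` for a monic
  basic irreducible ``h`` (:class:`RingContext`).  The residue of ``x``
  is a Teichmüller unit ``xi`` of multiplicative order ``2^m - 1``.
* the Graeffe (Hensel) lift taking a binary primitive polynomial to its
  basic irreducible over Z4 (:func:`graeffe_lift`).

Polynomials are exchanged as strings in a fixed dialect, e.g.
``"x^6+2x^5+x^4+x^3+3x+1"`` over Z4 or ``"x^3+ax^2+bx+b"`` over GF(4):
descending terms joined by ``+``, coefficient omitted when 1, exponent
omitted for ``x`` and the constant term.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "GF2",
    "Z4",
    "GF4",
    "Gf4Element",
    "gf4_add",
    "gf4_mul",
    "Poly",
    "PolyParseError",
    "DomainError",
    "parse_poly",
    "graeffe_lift",
    "FieldContext",
    "FieldElement",
    "RingContext",
    "RingElement",
    "ring_pow",
    "eval_poly",
    "symbol_ops",
]

# Coefficient domain tags
GF2 = "GF2"
Z4 = "Z4"
GF4 = "GF4"

_DOMAIN_VALUES = {GF2: (0, 1), Z4: (0, 1, 2, 3), GF4: (0, 1, 2, 3)}

# GF(4) multiplication, indices 0,1,a=2,b=3.  a*a=b, a*b=1, b*b=a.
GF4_MUL = np.array(
    [
        [0, 0, 0, 0],
        [0, 1, 2, 3],
        [0, 2, 3, 1],
        [0, 3, 1, 2],
    ],
    dtype=np.uint8,
)

_GF4_NAMES = {0: "0", 1: "1", 2: "a", 3: "b"}
_GF4_VALUES = {v: k for k, v in _GF4_NAMES.items()}


class DomainError(ValueError):
    """An element or polynomial is used outside its coefficient domain."""


class Gf4Element(int):
    """An element of GF(4); also usable wherever a plain 0..3 int is.

    ``Gf4Element(2)`` is ``a`` and ``Gf4Element(3)`` is ``b = a + 1``.
    Addition coincides with subtraction (characteristic 2, the Klein
    four-group additively).
    """

    def __new__(cls, value: int) -> "Gf4Element":
        if not 0 <= int(value) <= 3:
            raise DomainError(f"GF(4) element out of range: {value!r}")
        return super().__new__(cls, int(value))

    def __add__(self, other):  # type: ignore[override]
        return Gf4Element(int(self) ^ int(other))

    __radd__ = __add__
    __sub__ = __add__
    __rsub__ = __add__

    def __neg__(self):
        return self

    def __mul__(self, other):  # type: ignore[override]
        return Gf4Element(int(GF4_MUL[int(self), int(other)]))

    __rmul__ = __mul__

    def __repr__(self) -> str:
        return f"Gf4Element({_GF4_NAMES[int(self)]})"

    def __str__(self) -> str:
        return _GF4_NAMES[int(self)]


def gf4_add(x: int, y: int) -> Gf4Element:
    """Add two GF(4) elements (XOR of the 2-bit representations)."""
    return Gf4Element(x) + Gf4Element(y)


def gf4_mul(x: int, y: int) -> Gf4Element:
    """Multiply two GF(4) elements modulo ``x^2 + x + 1``."""
    return Gf4Element(x) * Gf4Element(y)


# ---------------------------------------------------------------------------
# Polynomials
# ---------------------------------------------------------------------------


class PolyParseError(ValueError):
    """A polynomial string does not conform to the dialect."""


@dataclass(frozen=True)
class Poly:
    """A polynomial over GF2, Z4 or GF(4).

    ``coeffs`` is stored in ascending order (``coeffs[i]`` multiplies
    ``x^i``) with no trailing zeros; the zero polynomial has an empty
    coefficient tuple and degree ``-inf``.
    """

    coeffs: tuple[int, ...]
    domain: str

    def __post_init__(self) -> None:
        if self.domain not in _DOMAIN_VALUES:
            raise DomainError(f"unknown coefficient domain {self.domain!r}")
        allowed = _DOMAIN_VALUES[self.domain]
        cleaned = tuple(int(c) for c in self.coeffs)
        for c in cleaned:
            if c not in allowed:
                raise DomainError(
                    f"coefficient {c} outside domain {self.domain}"
                )
        while cleaned and cleaned[-1] == 0:
            cleaned = cleaned[:-1]
        object.__setattr__(self, "coeffs", cleaned)

    @property
    def degree(self) -> float:
        return len(self.coeffs) - 1 if self.coeffs else float("-inf")

    @property
    def is_zero(self) -> bool:
        return not self.coeffs

    @property
    def is_monic(self) -> bool:
        return bool(self.coeffs) and self.coeffs[-1] == 1

    def __getitem__(self, exponent: int) -> int:
        if 0 <= exponent < len(self.coeffs):
            return self.coeffs[exponent]
        return 0

    def reduced_mod2(self) -> "Poly":
        """The image of a Z4 polynomial under coefficient reduction mod 2."""
        return Poly(tuple(c % 2 for c in self.coeffs), GF2)

    def __str__(self) -> str:
        if not self.coeffs:
            return "0"
        names = _GF4_NAMES if self.domain == GF4 else {i: str(i) for i in range(4)}
        terms = []
        for e in range(len(self.coeffs) - 1, -1, -1):
            c = self.coeffs[e]
            if c == 0:
                continue
            coef = "" if (c == 1 and e > 0) else names[c]
            if e == 0:
                terms.append(names[c])
            elif e == 1:
                terms.append(f"{coef}x")
            else:
                terms.append(f"{coef}x^{e}")
        return "+".join(terms)

    def __mul__(self, other: "Poly") -> "Poly":
        if self.domain != other.domain:
            raise DomainError(
                f"cannot multiply {self.domain} and {other.domain} polynomials"
            )
        if self.is_zero or other.is_zero:
            return Poly((), self.domain)
        out = [0] * (len(self.coeffs) + len(other.coeffs) - 1)
        for i, ci in enumerate(self.coeffs):
            if ci == 0:
                continue
            for j, cj in enumerate(other.coeffs):
                if cj == 0:
                    continue
                if self.domain == GF4:
                    out[i + j] ^= int(GF4_MUL[ci, cj])
                elif self.domain == Z4:
                    out[i + j] = (out[i + j] + ci * cj) % 4
                else:
                    out[i + j] ^= ci & cj
        return Poly(tuple(out), self.domain)

    def __add__(self, other: "Poly") -> "Poly":
        if self.domain != other.domain:
            raise DomainError(
                f"cannot add {self.domain} and {other.domain} polynomials"
            )
        L = max(len(self.coeffs), len(other.coeffs))
        if self.domain == Z4:
            out = [(self[i] + other[i]) % 4 for i in range(L)]
        else:
            out = [self[i] ^ other[i] for i in range(L)]
        return Poly(tuple(out), self.domain)


_TERM_RE = re.compile(r"^(?P<coef>[0-3ab]?)(?P<var>x(\^(?P<exp>\d+))?)?$")


def parse_poly(text: str, domain: str) -> Poly:
    """Parse a polynomial string in the fixed dialect.

    Raises :class:`PolyParseError` naming the offending term on malformed
    input, a coefficient outside ``domain``, or a repeated exponent.
    """
    if domain not in _DOMAIN_VALUES:
        raise DomainError(f"unknown coefficient domain {domain!r}")
    cleaned = text.replace(" ", "")
    if cleaned == "":
        raise PolyParseError("empty polynomial string")
    coeffs: dict[int, int] = {}
    for term in cleaned.split("+"):
        m = _TERM_RE.match(term)
        if m is None or term == "":
            raise PolyParseError(f"malformed term {term!r} in {text!r}")
        coef_tok, var = m.group("coef"), m.group("var")
        if coef_tok == "" and var is None:
            raise PolyParseError(f"malformed term {term!r} in {text!r}")
        if coef_tok == "":
            coef = 1
        elif coef_tok in ("a", "b"):
            if domain != GF4:
                raise PolyParseError(
                    f"coefficient {coef_tok!r} invalid over {domain} in term {term!r}"
                )
            coef = _GF4_VALUES[coef_tok]
        else:
            coef = int(coef_tok)
            if coef not in _DOMAIN_VALUES[domain]:
                raise PolyParseError(
                    f"coefficient {coef} outside {domain} in term {term!r}"
                )
        if var is None:
            exp = 0
        elif m.group("exp") is None:
            exp = 1
        else:
            exp = int(m.group("exp"))
        if exp in coeffs:
            raise PolyParseError(f"repeated exponent in term {term!r} of {text!r}")
        coeffs[exp] = coef
    deg = max(coeffs)
    return Poly(tuple(coeffs.get(i, 0) for i in range(deg + 1)), domain)


# ---------------------------------------------------------------------------
# Graeffe / Hensel lift
# ---------------------------------------------------------------------------


def graeffe_lift(f2: Poly) -> Poly:
    """Lift a binary primitive polynomial to its basic irreducible over Z4.

    Writing ``f2(x) = e(x^2) + x d(x^2)``, the lift is
    ``h(y) = +/-(e(y)^2 - y d(y)^2) mod 4``, with the sign chosen to make
    ``h`` monic.  ``h`` reduces to ``f2`` mod 2, and when ``f2`` is
    primitive a root of ``h`` in ``GR(4, deg f2)`` is a Teichmüller unit
    of order ``2^deg - 1``.
    """
    if f2.domain != GF2:
        raise DomainError("graeffe_lift expects a polynomial over GF2")
    if f2.is_zero or not f2.is_monic:
        raise DomainError("graeffe_lift expects a monic polynomial")
    if f2[0] == 0:
        raise DomainError("graeffe_lift input must not have a root at 0")
    e = f2.coeffs[0::2]
    d = f2.coeffs[1::2]

    def _square(p: Sequence[int]) -> list[int]:
        if not p:
            return []
        out = [0] * (2 * len(p) - 1)
        for i, ci in enumerate(p):
            for j, cj in enumerate(p):
                out[i + j] += ci * cj
        return out

    e2 = _square(e)
    d2 = _square(d)
    h = [0] * max(len(e2), len(d2) + 1)
    for i, c in enumerate(e2):
        h[i] += c
    for i, c in enumerate(d2):
        h[i + 1] -= c
    h = [c % 4 for c in h]
    while h and h[-1] == 0:
        h.pop()
    if h[-1] == 3:  # negate to restore monicity (odd-degree case)
        h = [(-c) % 4 for c in h]
    return Poly(tuple(h), Z4)


# ---------------------------------------------------------------------------
# GF(4^m)
# ---------------------------------------------------------------------------


class FieldContext:
    """The field GF(4^m) presented by a primitive polynomial over GF(4).

    Elements are packed integers: digit ``i`` (bits ``2i, 2i+1``) is the
    GF(4) coefficient of ``alpha^i`` in the residue basis, so addition of
    packed values is XOR.  Construction verifies that the residue of
    ``x`` (``alpha``) has multiplicative order exactly ``4^m - 1``.
    """

    def __init__(self, primitive_poly: Poly):
        if primitive_poly.domain != GF4:
            raise DomainError("FieldContext expects a polynomial over GF(4)")
        if not primitive_poly.is_monic:
            raise DomainError("primitive polynomial must be monic")
        self.primitive_poly = primitive_poly
        self.m = int(primitive_poly.degree)
        self.n = 4**self.m - 1
        # x^m = sum_i red[i] x^i  (char 2: minus is plus)
        red = [primitive_poly[i] for i in range(self.m)]

        def mul_alpha(v: int) -> int:
            hi = (v >> (2 * (self.m - 1))) & 3
            out = (v << 2) & ((1 << (2 * self.m)) - 1)
            if hi:
                for i, r in enumerate(red):
                    if r:
                        out ^= int(GF4_MUL[hi, r]) << (2 * i)
            return out

        pows = [1]
        cur = 1
        for _ in range(self.n - 1):
            cur = mul_alpha(cur)
            if cur == 1:
                break
            pows.append(cur)
        if len(pows) != self.n or mul_alpha(pows[-1]) != 1:
            raise DomainError(
                f"{primitive_poly} is not primitive over GF(4): "
                f"order of alpha is {len(pows)}, expected {self.n}"
            )
        self.alpha_pows: list[int] = pows
        self.log: dict[int, int] = {v: i for i, v in enumerate(pows)}

    # -- element arithmetic on packed ints ---------------------------------
    @staticmethod
    def add(u: int, v: int) -> int:
        return u ^ v

    def mul(self, u: int, v: int) -> int:
        if u == 0 or v == 0:
            return 0
        return self.alpha_pows[(self.log[u] + self.log[v]) % self.n]

    def inv(self, u: int) -> int:
        if u == 0:
            raise ZeroDivisionError("inverting 0 in GF(4^m)")
        return self.alpha_pows[(-self.log[u]) % self.n]

    def alpha(self, exponent: int = 1) -> "FieldElement":
        return FieldElement(self.alpha_pows[exponent % self.n], self)

    def element(self, packed: int) -> "FieldElement":
        return FieldElement(packed, self)

    def scale(self, c: int, u: int) -> int:
        """Multiply a packed element by a GF(4) scalar (digit-wise)."""
        if c == 0 or u == 0:
            return 0
        if c == 1:
            return u
        out = 0
        for i in range(self.m):
            d = (u >> (2 * i)) & 3
            if d:
                out |= int(GF4_MUL[c, d]) << (2 * i)
        return out

    def minimal_polynomial(self, exponent: int) -> Poly:
        """Minimal polynomial of ``alpha^exponent`` over GF(4).

        The conjugates are ``alpha^(exponent * 4^i)``; the product of the
        corresponding linear factors has GF(4) coefficients.
        """
        conjs: list[int] = []
        c = exponent % self.n
        while c not in conjs:
            conjs.append(c)
            c = (c * 4) % self.n
        # coefficients live in GF(4^m) during the product
        poly: list[int] = [1]
        for e in conjs:
            root = self.alpha_pows[e]
            new = [0] * (len(poly) + 1)
            for i, co in enumerate(poly):
                new[i + 1] ^= co
                new[i] ^= self.mul(co, root)
            poly = new
        out = []
        for co in poly:
            if co >> 2:
                raise DomainError("minimal polynomial coefficient not in GF(4)")
            out.append(co & 3)
        return Poly(tuple(out), GF4)

    def __repr__(self) -> str:
        return f"FieldContext(GF(4^{self.m}), p(x)={self.primitive_poly})"


@dataclass(frozen=True)
class FieldElement:
    """An element of GF(4^m), packed 2 bits per residue-basis digit."""

    value: int
    ctx: FieldContext

    @property
    def is_zero(self) -> bool:
        return self.value == 0

    def __add__(self, other: "FieldElement") -> "FieldElement":
        return FieldElement(self.value ^ other.value, self.ctx)

    __sub__ = __add__

    def __neg__(self) -> "FieldElement":
        return self

    def __mul__(self, other: "FieldElement") -> "FieldElement":
        return FieldElement(self.ctx.mul(self.value, other.value), self.ctx)

    def __rmul__(self, scalar: int) -> "FieldElement":
        return FieldElement(self.ctx.scale(int(scalar), self.value), self.ctx)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, FieldElement):
            return self.value == other.value
        if other == 0:
            return self.value == 0
        return NotImplemented

    def __hash__(self) -> int:
        return hash(("FieldElement", self.value))


# ---------------------------------------------------------------------------
# GR(4, m)
# ---------------------------------------------------------------------------


class RingContext:
    """The Galois ring GR(4, m) = Z4[x]/(h(x)).

    ``h`` is the Graeffe lift of a binary primitive polynomial of degree
    ``m``; the residue of ``x`` is the Teichmüller unit ``xi`` of
    multiplicative order ``n = 2^m - 1``.  Elements are coordinate tuples
    of length ``m`` over Z4 in the residue basis.
    """

    def __init__(self, binary_primitive: Poly):
        if binary_primitive.domain != GF2:
            raise DomainError("RingContext expects a binary polynomial")
        self.binary_primitive = binary_primitive
        self.basic_irreducible = graeffe_lift(binary_primitive)
        self.m = int(binary_primitive.degree)
        self.n = 2**self.m - 1
        h = self.basic_irreducible
        # x^m = -(h_0 + ... + h_{m-1} x^{m-1}) mod 4
        self._red = tuple((-h[i]) % 4 for i in range(self.m))

        xi = tuple(1 if i == 1 else 0 for i in range(self.m))
        one = tuple(1 if i == 0 else 0 for i in range(self.m))
        pows = [one]
        cur = one
        for _ in range(self.n - 1):
            cur = self._mul_x(cur)
            if cur == one:
                break
            pows.append(cur)
        if len(pows) != self.n or self._mul_x(pows[-1]) != one:
            raise DomainError(
                f"{binary_primitive} is not primitive: xi has order "
                f"{len(pows)}, expected {self.n}"
            )
        self.xi_pows: list[tuple[int, ...]] = pows

    def _mul_x(self, coords: tuple[int, ...]) -> tuple[int, ...]:
        hi = coords[-1]
        out = [0] + list(coords[:-1])
        if hi:
            for i, r in enumerate(self._red):
                out[i] = (out[i] + hi * r) % 4
        return tuple(out)

    # -- coordinate arithmetic ---------------------------------------------
    @staticmethod
    def add(u: tuple[int, ...], v: tuple[int, ...]) -> tuple[int, ...]:
        return tuple((a + b) % 4 for a, b in zip(u, v))

    @staticmethod
    def neg(u: tuple[int, ...]) -> tuple[int, ...]:
        return tuple((-a) % 4 for a in u)

    @staticmethod
    def scale(c: int, u: tuple[int, ...]) -> tuple[int, ...]:
        return tuple((c * a) % 4 for a in u)

    def mul(self, u: tuple[int, ...], v: tuple[int, ...]) -> tuple[int, ...]:
        m = self.m
        conv = [0] * (2 * m - 1)
        for i, a in enumerate(u):
            if a:
                for j, b in enumerate(v):
                    conv[i + j] = (conv[i + j] + a * b) % 4
        for d in range(2 * m - 2, m - 1, -1):
            c = conv[d]
            if c:
                conv[d] = 0
                for i, r in enumerate(self._red):
                    conv[d - m + i] = (conv[d - m + i] + c * r) % 4
        return tuple(conv[:m])

    def zero(self) -> "RingElement":
        return RingElement(tuple(0 for _ in range(self.m)), self)

    def one(self) -> "RingElement":
        return RingElement(self.xi_pows[0], self)

    @property
    def xi(self) -> "RingElement":
        return RingElement(self.xi_pows[1 % self.n], self)

    def element(self, coords: Iterable[int]) -> "RingElement":
        return RingElement(tuple(int(c) % 4 for c in coords), self)

    @cached_property
    def xi_log(self) -> dict[tuple[int, ...], int]:
        return {v: i for i, v in enumerate(self.xi_pows)}

    @cached_property
    def teichmuller_set(self) -> frozenset[tuple[int, ...]]:
        """{0, 1, xi, ..., xi^(n-1)} — has exactly 2^m elements."""
        return frozenset(self.xi_pows) | {tuple(0 for _ in range(self.m))}

    @cached_property
    def xi_pow_matrix(self) -> np.ndarray:
        """(n, m) uint8 array, row j = coordinates of xi^j."""
        return np.array(self.xi_pows, dtype=np.uint8)

    def __repr__(self) -> str:
        return (
            f"RingContext(GR(4,{self.m}), h(x)={self.basic_irreducible})"
        )


@dataclass(frozen=True)
class RingElement:
    """An element of GR(4, m) as Z4 coordinates in the residue basis."""

    coords: tuple[int, ...]
    ctx: RingContext

    @property
    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coords)

    @property
    def is_unit(self) -> bool:
        # unit iff nonzero image under the mod-2 reduction onto GF(2^m)
        return any(c % 2 for c in self.coords)

    def __add__(self, other: "RingElement") -> "RingElement":
        return RingElement(RingContext.add(self.coords, other.coords), self.ctx)

    def __sub__(self, other: "RingElement") -> "RingElement":
        return self + (-other)

    def __neg__(self) -> "RingElement":
        return RingElement(RingContext.neg(self.coords), self.ctx)

    def __mul__(self, other: "RingElement") -> "RingElement":
        return RingElement(self.ctx.mul(self.coords, other.coords), self.ctx)

    def __rmul__(self, scalar: int) -> "RingElement":
        return RingElement(RingContext.scale(int(scalar) % 4, self.coords), self.ctx)

    def reduced_mod2(self) -> tuple[int, ...]:
        return tuple(c % 2 for c in self.coords)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, RingElement):
            return self.coords == other.coords
        if other == 0:
            return self.is_zero
        return NotImplemented

    def __hash__(self) -> int:
        return hash(("RingElement", self.coords))


def ring_pow(ctx: RingContext, exponent: int) -> RingElement:
    """``xi^exponent`` (exponent reduced mod ``n``); table-backed."""
    return RingElement(ctx.xi_pows[exponent % ctx.n], ctx)


Element = Union[FieldElement, RingElement]


def eval_poly(p: Poly, point: Element) -> Element:
    """Horner evaluation of ``p`` at a ring or field element.

    The coefficient domain must embed in the point's algebra: GF2/Z4
    coefficients evaluate at :class:`RingElement` points, GF2/GF4
    coefficients at :class:`FieldElement` points.
    """
    if isinstance(point, RingElement):
        if p.domain not in (Z4, GF2):
            raise DomainError(f"{p.domain} coefficients do not embed in GR(4,m)")
        ctx = point.ctx
        acc = ctx.zero()
        one = ctx.one()
        for c in reversed(p.coeffs or (0,)):
            acc = acc * point + c * one
        return acc
    if isinstance(point, FieldElement):
        if p.domain not in (GF4, GF2):
            raise DomainError(f"{p.domain} coefficients do not embed in GF(4^m)")
        fctx = point.ctx
        val = 0
        for c in reversed(p.coeffs or (0,)):
            val = fctx.add(fctx.mul(val, point.value), c)
        return FieldElement(val, fctx)
    raise DomainError(f"cannot evaluate at {type(point).__name__}")


# ---------------------------------------------------------------------------
# Vectorized symbol-level operations (shared by codes/decoding)
# ---------------------------------------------------------------------------


class _Z4Ops:
    """Arithmetic on uint8 arrays of Z4 symbols."""

    domain = Z4

    @staticmethod
    def add(a, b):
        return (a.astype(np.int16) + b) % 4

    @staticmethod
    def neg(a):
        return (-a.astype(np.int16)) % 4

    @staticmethod
    def scale(c, a):
        return (int(c) * a.astype(np.int16)) % 4


class _Gf4Ops:
    """Arithmetic on uint8 arrays of GF(4) symbols."""

    domain = GF4

    @staticmethod
    def add(a, b):
        return np.bitwise_xor(a, b)

    @staticmethod
    def neg(a):
        return a

    @staticmethod
    def scale(c, a):
        return GF4_MUL[int(c), a]


def symbol_ops(domain: str):
    """Vectorized add/neg/scale for a symbol domain (Z4 or GF4)."""
    if domain == Z4:
        return _Z4Ops
    if domain == GF4:
        return _Gf4Ops
    raise DomainError(f"no symbol ops for domain {domain!r}")
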