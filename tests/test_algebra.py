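"""Unit and property tests for GF(4), polynomials, the Graeffe lift,
GF(4^m) and GR(4, m)."""

import itertools

import numpy as np
import pytest
import sympy
from hypothesis import given
from hypothesis import strategies as st

from dnasga.algebra import (
    GF2,
    GF4,
    Z4,
    DomainError,
    FieldContext,
    Gf4Element,
    Poly,
    PolyParseError,
    RingContext,
    eval_poly,
    gf4_mul,
    graeffe_lift,
    parse_poly,
    ring_pow,
)

A, B = Gf4Element(2), Gf4Element(3)


class TestGf4:
    @pytest.mark.parametrize(
        "x, y, expected",
        [(A, A, B), (Gf4Element(1), B, B), (A, B, Gf4Element(1))],
    )
    def test_multiplication_examples(self, x, y, expected):
        assert gf4_mul(x, y) == expected

    def test_additive_group_is_klein_four(self):
        # every element is its own additive inverse; addition closed
        for x in map(Gf4Element, range(4)):
            assert x + x == 0
            for y in map(Gf4Element, range(4)):
                assert 0 <= x + y <= 3

    def test_multiplicative_group_cyclic_of_order_3(self):
        assert A * A == B and A * A * A == 1
        orders = {x: next(
            k for k in (1, 2, 3) if _pow(x, k) == 1
        ) for x in (Gf4Element(1), A, B)}
        assert sorted(orders.values()) == [1, 3, 3]

    def test_field_axioms_sampled(self):
        elems = [Gf4Element(i) for i in range(4)]
        for x, y, z in itertools.product(elems, repeat=3):
            assert x * (y + z) == x * y + x * z
            assert (x * y) * z == x * (y * z)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            Gf4Element(4)


def _pow(x, k):
    out = Gf4Element(1)
    for _ in range(k):
        out = out * x
    return out


class TestPolyParsing:
    def test_z4_generator_polynomial(self):
        p = parse_poly("x^6+2x^5+x^4+x^3+3x+1", Z4)
        assert p.coeffs[::-1] == (1, 2, 1, 1, 0, 3, 1)  # x^6 down to x^0
        assert p.degree == 6

    def test_gf4_primitive_polynomial(self):
        p = parse_poly("x^3+ax^2+bx+b", GF4)
        assert p.coeffs[::-1] == (1, 2, 3, 3)
        assert str(p) == "x^3+ax^2+bx+b"

    def test_zero_polynomial(self):
        p = parse_poly("0", Z4)
        assert p.is_zero and p.degree == float("-inf")
        assert str(p) == "0"

    @pytest.mark.parametrize(
        "text, domain",
        [
            ("x^2+zx", Z4),
            ("x^2++1", Z4),
            ("2x+1", GF2),
            ("ax+1", Z4),
            ("x^2+x^2", Z4),  # repeated exponent
            ("", Z4),
        ],
    )
    def test_parse_errors_name_offender(self, text, domain):
        with pytest.raises(PolyParseError):
            parse_poly(text, domain)

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=12),
        st.sampled_from([Z4, GF4]),
    )
    def test_print_parse_roundtrip(self, coeffs, domain):
        p = Poly(tuple(coeffs), domain)
        if p.is_zero:
            assert parse_poly(str(p), domain).is_zero
        else:
            assert parse_poly(str(p), domain) == p


def _sympy_graeffe(f2: Poly) -> Poly:
    """Independent oracle: prod over roots r of f2 of (y - r^2), via the
    resultant Res_x(f2(x), y - x^2), reduced mod 4 and made monic."""
    x, y = sympy.symbols("x y")
    fx = sum(int(c) * x**i for i, c in enumerate(f2.coeffs))
    res = sympy.Poly(sympy.resultant(fx, y - x**2, x), y)
    coeffs = [int(c) % 4 for c in reversed(res.all_coeffs())]
    if coeffs[-1] == 3:
        coeffs = [(-c) % 4 for c in coeffs]
    return Poly(tuple(coeffs), Z4)


class TestGraeffeLift:
    @pytest.mark.parametrize(
        "binary, lifted",
        [
            ("x^6+x^4+x^3+x+1", "x^6+2x^5+x^4+x^3+3x+1"),
            (
                "x^10+x^9+x^8+x^7+x^6+x^4+x^3+x+1",
                "x^10+x^9+x^8+3x^7+x^6+x^4+x^3+3x+1",
            ),
            ("x+1", "x+3"),
        ],
    )
    def test_published_pairs(self, binary, lifted):
        assert str(graeffe_lift(parse_poly(binary, GF2))) == lifted

    def test_lift_reduces_to_input_mod_2(self, registry):
        for entry in registry.values():
            if entry.kind != "ring":
                continue
            f2 = parse_poly(entry.primitive, GF2)
            assert graeffe_lift(f2).reduced_mod2() == f2

    def test_against_resultant_oracle(self, registry):
        for entry in registry.values():
            if entry.kind != "ring":
                continue
            f2 = parse_poly(entry.primitive, GF2)
            assert graeffe_lift(f2) == _sympy_graeffe(f2)

    @pytest.mark.parametrize("bad", ["x^2+x", "0"])
    def test_rejects_zero_constant_or_zero(self, bad):
        with pytest.raises(DomainError):
            graeffe_lift(parse_poly(bad, GF2))

    def test_rejects_wrong_domain(self):
        with pytest.raises(DomainError):
            graeffe_lift(parse_poly("x^2+x+1", Z4))


@pytest.fixture(scope="module")
def ring6():
    return RingContext(parse_poly("x^6+x^4+x^3+x+1", GF2))


@pytest.fixture(scope="module")
def field3():
    return FieldContext(parse_poly("x^3+ax^2+bx+b", GF4))


class TestRingContext:
    def test_xi_has_exact_order_63(self, ring6):
        xi = ring6.xi
        one = ring6.one()
        for d in (1, 3, 7, 9, 21):  # proper divisors of 63
            assert _ring_power(xi, d) != one
        assert _ring_power(xi, 63) == one

    def test_ring_pow_identities(self, ring6):
        assert ring_pow(ring6, 0) == ring6.one()
        assert ring_pow(ring6, ring6.n) == ring6.one()
        assert ring_pow(ring6, 1) == ring6.xi
        assert ring_pow(ring6, -1) * ring6.xi == ring6.one()

    def test_teichmuller_set_size(self, ring6):
        assert len(ring6.teichmuller_set) == 2**ring6.m

    def test_basic_irreducible_annihilates_conjugates(self, ring6):
        h = ring6.basic_irreducible
        for k in range(ring6.m):  # xi, xi^2, xi^4, ..., xi^(2^(m-1))
            assert eval_poly(h, ring_pow(ring6, 2**k)).is_zero

    def test_two_torsion(self, ring6):
        rng = np.random.default_rng(11)
        for _ in range(20):
            u = ring6.element(rng.integers(0, 4, ring6.m))
            assert ((2 * u) + (2 * u)).is_zero

    def test_mod2_reduction_is_homomorphism(self, ring6):
        rng = np.random.default_rng(12)
        for _ in range(30):
            u = ring6.element(rng.integers(0, 4, ring6.m))
            v = ring6.element(rng.integers(0, 4, ring6.m))
            assert (u * v).reduced_mod2() == _gf2m_mul(ring6, u, v)
            assert (u + v).reduced_mod2() == tuple(
                (a + b) % 2 for a, b in zip(u.coords, v.coords)
            )
            # Frobenius compatibility: (u+v)^2 = u^2 + v^2 mod 2
            assert ((u + v) * (u + v)).reduced_mod2() == tuple(
                (a + b) % 2 for a, b in zip((u * u).coords, (v * v).coords)
            )

    def test_non_primitive_rejected(self):
        # x^2+x+1 has order-3 roots, not 2^2-1=3... use a reducible poly:
        # x^4+x^2+1 = (x^2+x+1)^2 over GF(2)
        with pytest.raises(DomainError):
            RingContext(parse_poly("x^4+x^2+1", GF2))


def _ring_power(x, k):
    out = x.ctx.one()
    for _ in range(k):
        out = out * x
    return out


def _gf2m_mul(ctx, u, v):
    """Schoolbook product in GF(2^m) = GF(2)[x]/(binary_primitive)."""
    m = ctx.m
    red = [c % 2 for c in ctx.binary_primitive.coeffs[:m]]
    conv = [0] * (2 * m - 1)
    for i, a in enumerate(u.reduced_mod2()):
        if a:
            for j, b in enumerate(v.reduced_mod2()):
                conv[i + j] ^= a & b
    for d in range(2 * m - 2, m - 1, -1):
        if conv[d]:
            conv[d] = 0
            for i, r in enumerate(red):
                conv[d - m + i] ^= r
    return tuple(conv[:m])


class TestFieldContext:
    def test_alpha_has_exact_order_63(self, field3):
        assert field3.n == 63
        one = field3.alpha(0)
        for d in (1, 3, 7, 9, 21):
            assert field3.alpha(d) != one or d % 63 == 0
        # exact order verified at construction; spot-check the table
        assert len(set(field3.alpha_pows)) == 63

    def test_primitive_poly_annihilates_alpha(self, field3):
        assert eval_poly(field3.primitive_poly, field3.alpha()).is_zero

    def test_registry_field_primitives_are_primitive(self, registry):
        # fixed presentation a = x, b = a + 1; no a<->b swap needed
        for entry in registry.values():
            if entry.kind == "field":
                ctx = FieldContext(parse_poly(entry.primitive, GF4))
                assert ctx.n == 63

    def test_non_primitive_rejected(self):
        # x^3+ax+... pick an irreducible-but-imprimitive or reducible poly
        with pytest.raises(DomainError):
            FieldContext(parse_poly("x^2+1", GF4))  # (x+1)^2 over GF(4)


class TestEvalPoly:
    def test_zero_poly_evaluates_to_zero(self, ring6, field3):
        zero = Poly((), Z4)
        assert eval_poly(zero, ring6.xi).is_zero
        assert eval_poly(Poly((), GF4), field3.alpha()).is_zero

    def test_monomial_matches_power_table(self, ring6):
        p = parse_poly("x^2", Z4)
        assert eval_poly(p, ring6.xi) == ring_pow(ring6, 2)

    def test_domain_mismatch(self, ring6, field3):
        with pytest.raises(DomainError):
            eval_poly(parse_poly("ax+1", GF4), ring6.xi)
        with pytest.raises(DomainError):
            eval_poly(parse_poly("2x+1", Z4), field3.alpha())
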