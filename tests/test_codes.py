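"""Code construction, encoding, syndromes, membership, minimum weight."""

import numpy as np
import pytest

from dnasga.algebra import GF2, GF4, Z4, graeffe_lift, parse_poly
from dnasga.codes import (
    CodeRegistryEntry,
    InvalidCodeError,
    build_code,
    derive_generator,
    encode,
    is_codeword,
    load_registry,
    min_weight_certificate,
    syndromes,
)


def _rand_codeword(code, rng):
    return encode(rng.integers(0, 4, code.k, dtype=np.uint8), code)


def _add_symbol(code, vec, pos, e):
    out = vec.copy()
    if code.symbol_domain == Z4:
        out[pos] = (int(out[pos]) + e) % 4
    else:
        out[pos] = int(out[pos]) ^ e
    return out


class TestRegistry:
    def test_fifteen_presets(self, registry):
        assert len(registry) == 15

    def test_every_entry_builds(self, codes):
        for code in codes.values():
            assert code.designed_distance == 3

    def test_dimension_matches_generator_degree(self, codes):
        for code in codes.values():
            assert code.k + int(code.generator_poly.degree) == code.n

    @pytest.mark.parametrize(
        "key, n, k", [("MDH", 1023, 1013), ("S02.b", 63, 57), ("S02.a", 63, 57)]
    )
    def test_published_parameters(self, codes, key, n, k):
        code = codes[key]
        assert (code.n, code.k, code.designed_distance) == (n, k, 3)

    def test_ring_generators_equal_graeffe_lift(self, registry):
        for entry in registry.values():
            if entry.kind != "ring":
                continue
            lift = graeffe_lift(parse_poly(entry.primitive, GF2))
            assert str(lift) == entry.generator

    def test_printed_generators_equal_derived(self, registry, codes):
        for key, entry in registry.items():
            derived = derive_generator(codes[key].context)
            assert str(derived) == entry.generator

    def test_mdh_generator_printed_form(self, codes):
        assert (
            str(codes["MDH"].generator_poly)
            == "x^10+x^9+x^8+3x^7+x^6+x^4+x^3+3x+1"
        )

    def test_field_generator_s02a(self, codes):
        assert str(codes["S02.a"].generator_poly) == "x^6+x^5+1"

    def test_mismatched_generator_warns(self, registry):
        entry = registry["S02.b"]
        # S02.g's generator also divides x^63 - 1 but is not S02.b's lift
        fake = CodeRegistryEntry(
            key="fake",
            gi=entry.gi,
            organism=entry.organism,
            seq_class=entry.seq_class,
            labeling=entry.labeling,
            kind="ring",
            primitive=entry.primitive,
            generator=registry["S02.g"].generator,
        )
        with pytest.warns(UserWarning, match="differs from derived"):
            code = build_code(fake)
        assert str(code.generator_poly) == registry["S02.g"].generator

    def test_non_divisor_generator_rejected(self, registry):
        entry = registry["S02.b"]
        fake = CodeRegistryEntry(
            key="bad",
            gi=entry.gi,
            organism=entry.organism,
            seq_class=entry.seq_class,
            labeling=entry.labeling,
            kind="ring",
            primitive=entry.primitive,
            generator="x^2+1",  # (x+1)^2 mod 2 cannot divide squarefree x^63-1
        )
        with pytest.warns(UserWarning):
            with pytest.raises(InvalidCodeError):
                build_code(fake)


class TestEncode:
    def test_zero_message_gives_zero_codeword(self, codes):
        for code in codes.values():
            word = encode(np.zeros(code.k, dtype=np.uint8), code)
            assert not word.any()

    def test_unit_message_gives_generator(self, codes):
        for key in ("S02.b", "S02.a"):
            code = codes[key]
            msg = np.zeros(code.k, dtype=np.uint8)
            msg[-1] = 1  # m(x) = 1
            word = encode(msg, code)
            deg = int(code.generator_poly.degree)
            assert not word[: code.n - deg - 1].any()
            assert tuple(word[code.n - deg - 1 :]) == code.generator_poly.coeffs[::-1]

    def test_random_codewords_are_codewords(self, codes):
        rng = np.random.default_rng(21)
        for code in codes.values():
            for _ in range(3):
                assert is_codeword(_rand_codeword(code, rng), code)

    def test_wrong_length_rejected(self, codes):
        with pytest.raises(ValueError):
            encode(np.zeros(10, dtype=np.uint8), codes["S02.b"])


class TestSyndromes:
    def test_zero_vector(self, codes):
        for key in ("S02.b", "S02.a", "MDH"):
            code = codes[key]
            s1, s2 = syndromes(np.zeros(code.n, dtype=np.uint8), code)
            assert s1.is_zero and s2.is_zero

    def test_codewords_have_zero_syndromes(self, codes):
        rng = np.random.default_rng(22)
        for code in codes.values():
            s1, s2 = syndromes(_rand_codeword(code, rng), code)
            assert s1.is_zero and s2.is_zero

    def test_single_term_vector(self, codes):
        rng = np.random.default_rng(23)
        for key in ("S02.b", "S02.a", "MDH"):
            code = codes[key]
            for _ in range(5):
                j = int(rng.integers(0, code.n))
                e = int(rng.integers(1, 4))
                vec = np.zeros(code.n, dtype=np.uint8)
                vec[code.n - 1 - j] = e  # e * x^j
                s1, s2 = syndromes(vec, code)
                assert s1 == e * code.beta_power(j)
                assert s2 == e * code.beta_power(2 * j)

    def test_membership_routes_agree(self, codes):
        """Divisibility by g(x) iff both syndromes vanish (dual route)."""
        rng = np.random.default_rng(24)
        for code in codes.values():
            vectors = [_rand_codeword(code, rng)]
            vectors.append(rng.integers(0, 4, code.n, dtype=np.uint8))
            vectors.append(_add_symbol(code, vectors[0], 5, 2))
            for vec in vectors:
                s1, s2 = syndromes(vec, code)
                assert is_codeword(vec, code) == (s1.is_zero and s2.is_zero)


class TestCodeProperties:
    def test_cyclic_shift_closure(self, codes):
        rng = np.random.default_rng(25)
        for code in codes.values():
            word = _rand_codeword(code, rng)
            assert is_codeword(np.roll(word, 1), code)
            assert is_codeword(np.roll(word, -7), code)

    def test_linearity(self, codes):
        rng = np.random.default_rng(26)
        for code in codes.values():
            u, v = _rand_codeword(code, rng), _rand_codeword(code, rng)
            total = (u + v) % 4 if code.symbol_domain == Z4 else u ^ v
            assert is_codeword(total.astype(np.uint8), code)

    def test_weight1_offsets_are_noncodewords(self, codes):
        rng = np.random.default_rng(27)
        for code in codes.values():
            word = _rand_codeword(code, rng)
            pos = int(rng.integers(0, code.n))
            e = int(rng.integers(1, 4))
            assert not is_codeword(_add_symbol(code, word, pos, e), code)

    def test_generator_vector_is_codeword(self, codes):
        for code in codes.values():
            vec = np.zeros(code.n, dtype=np.uint8)
            deg = int(code.generator_poly.degree)
            vec[code.n - deg - 1 :] = code.generator_poly.coeffs[::-1]
            assert is_codeword(vec, code)


class TestMinWeight:
    @pytest.mark.parametrize("key", ["S02.b", "S02.a", "MDH"])
    def test_certificate(self, codes, key):
        code = codes[key]
        cert = min_weight_certificate(code)
        assert cert.no_weight_le_2, cert.refutation
        assert cert.weight3_vector is not None
        assert int(np.count_nonzero(cert.weight3_vector)) == 3
        assert is_codeword(cert.weight3_vector, code)
        assert cert.min_weight == 3

    def test_signature_table_excludes_weight1(self, codes):
        # ring codes: injectivity and nonzero keys (no e * xi^j vanishes)
        for key in ("S02.b", "MDH"):
            code = codes[key]
            table = code.error_signatures
            assert len(table) == 3 * code.n
            assert tuple(0 for _ in range(code.context.m)) not in table

    def test_signature_table_ring_only(self, codes):
        # GF(4)* lies inside the alpha power table, so no injective
        # one-syndrome signature exists for field codes
        with pytest.raises(InvalidCodeError):
            codes["S02.a"].error_signatures
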