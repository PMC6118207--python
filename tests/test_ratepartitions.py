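"""Rate-span partitioning: boundary formulas, scheme assembly, dialects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tigerpart.ratepartitions import (
    InvalidDivisionFactorError,
    build_scheme,
    compress_ranges,
    first_boundary,
    next_boundary,
    read_scheme,
    write_scheme,
)
from tigerpart.tiger import SiteRates


def reference_scheme(rates, d, remainder_fraction=0.10):
    """Straight-line reimplementation of the span iteration (oracle)."""
    rates = list(rates)
    total = len(rates)
    x, y = max(rates), min(rates)
    if x == y:
        return [list(range(1, total + 1))]
    unassigned = set(range(1, total + 1))
    out = []
    p = 0
    while True:
        p += 1
        z = x - (x - y) / d if p == 1 else x - (x - y) / (d + 0.3 * p)
        span = sorted(i for i in unassigned if z < rates[i - 1] <= x)
        if span:
            out.append(span)
        unassigned -= set(span)
        if (
            len(unassigned) < remainder_fraction * total
            or z - y < 1e-12
            or p > 1000
        ):
            if unassigned:
                out.append(sorted(unassigned))
            return out
        x = z


class TestBoundaries:
    def test_worked_example_first_span(self):
        assert first_boundary(1.0, 0.2, 1.5) == pytest.approx(0.4667, abs=5e-5)

    def test_worked_example_second_span(self):
        z1 = first_boundary(1.0, 0.2, 1.5)
        assert next_boundary(z1, 0.2, 1.5, 2) == pytest.approx(0.3397, abs=5e-5)

    def test_zero_range_collapses(self):
        assert first_boundary(0.7, 0.7, 2.0) == 0.7
        assert next_boundary(0.7, 0.7, 2.0, 3) == 0.7

    @pytest.mark.parametrize("d", [1.0, 0.5, -2.0])
    def test_division_factor_must_exceed_one(self, d):
        with pytest.raises(InvalidDivisionFactorError):
            first_boundary(1.0, 0.0, d)
        with pytest.raises(InvalidDivisionFactorError):
            next_boundary(1.0, 0.0, d, 2)

    def test_direct_arithmetic(self):
        assert next_boundary(1.0, 0.0, 2.0, 3) == pytest.approx(1 - 1 / 2.9)

    def test_span_width_recurrence(self):
        # x_{p+1} - y = (x_p - y) (1 - 1/(d + 0.3 p)) for p >= 2
        x, y, d = 0.9, 0.1, 2.5
        for p in range(2, 8):
            z = next_boundary(x, y, d, p)
            assert z - y == pytest.approx((x - y) * (1 - 1 / (d + 0.3 * p)))
            assert z < x
            x = z


class TestBuildScheme:
    def test_worked_example_membership(self):
        rates = SiteRates(np.array([1.0, 0.95, 0.5, 0.47, 0.40, 0.35,
                                    0.30, 0.25, 0.22, 0.2]))
        scheme = build_scheme(rates, d=1.5)
        # first span (0.4667, 1.0]
        assert set(scheme.sites("p1")) == {1, 2, 3, 4}
        # second span (0.3397, 0.4667]
        assert set(scheme.sites("p2")) == {5, 6}

    def test_all_equal_rates_single_partition(self):
        scheme = build_scheme(SiteRates(np.full(50, 0.3)), d=2.0)
        assert len(scheme) == 1
        assert scheme.sites("p1") == tuple(range(1, 51))

    def test_matches_straight_line_oracle(self):
        rates = [round(1.0 - 0.1 * (i % 10), 10) for i in range(100)]
        for d in (1.5, 2.0, 3.0, 4.0, 4.5):
            scheme = build_scheme(SiteRates(np.array(rates)), d=d)
            expected = reference_scheme(rates, d)
            got = [list(sites) for _, sites, _ in scheme.subsets]
            assert got == expected

    def test_minimum_rate_sites_reachable_only_via_remainder(self):
        rates = np.concatenate([np.full(30, 0.0), np.linspace(0.5, 1, 70)])
        scheme = build_scheme(SiteRates(rates), d=2.0)
        last = scheme.subsets[-1]
        assert set(range(1, 31)) <= set(last[1])
        assert last[2].is_remainder

    def test_invalid_inputs(self):
        with pytest.raises(InvalidDivisionFactorError):
            build_scheme(SiteRates(np.array([0.5, 1.0])), d=1.0)
        with pytest.raises(ValueError):
            build_scheme([], d=2.0)

    @settings(max_examples=60, deadline=None)
    @given(
        rates=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=120,
        ),
        d=st.floats(min_value=1.01, max_value=25.0, allow_nan=False),
    )
    def test_exhaustive_and_disjoint(self, rates, d):
        scheme = build_scheme(SiteRates(np.array(rates)), d=d)
        seen: set[int] = set()
        for _name, sites, _span in scheme.subsets:
            assert sites, "no empty subsets in output"
            assert seen.isdisjoint(sites)
            seen.update(sites)
        assert seen == set(range(1, len(rates) + 1))
        assert scheme == build_scheme(SiteRates(np.array(rates)), d=d)

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        d1=st.floats(min_value=1.1, max_value=4.0),
        extra=st.floats(min_value=0.1, max_value=5.0),
    )
    def test_larger_d_never_fewer_iterated_spans(self, seed, d1, extra):
        rng = np.random.default_rng(seed)
        rates = SiteRates(rng.random(200))
        def n_iterated(d):
            return sum(
                1 for _, _, span in build_scheme(rates, d=d).subsets
                if span is not None and not span.is_remainder
            )
        assert n_iterated(d1 + extra) >= n_iterated(d1)

    def test_mean_rate_ordered_slow_to_fast(self):
        rng = np.random.default_rng(7)
        rates = SiteRates(rng.random(500))
        scheme = build_scheme(rates, d=3.0)
        means = [
            np.mean([rates.rates[s - 1] for s in sites])
            for _, sites, _ in scheme.subsets
        ]
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestSchemeFiles:
    @pytest.fixture
    def scheme(self):
        rates = SiteRates(np.array([1.0, 1.0, 1.0, 0.2, 0.3, 0.25, 1.0,
                                    0.9, 0.88, 0.2]))
        return build_scheme(rates, d=2.0)

    def test_range_compression(self):
        assert compress_ranges([1, 2, 3, 7]) == [(1, 3), (7, 7)]

    def test_raxml_line_format(self, tmp_path, scheme):
        out = tmp_path / "scheme.txt"
        write_scheme(scheme, "raxml", out)
        first = out.read_text().splitlines()[0]
        assert first == "DNA, p1 = 1-3,7-9"

    @pytest.mark.parametrize("fmt", ["raxml", "nexus", "pfinder"])
    def test_round_trip_through_reader(self, tmp_path, scheme, fmt):
        out = tmp_path / f"scheme.{fmt}"
        write_scheme(scheme, fmt, out)
        back = read_scheme(out, format="auto")
        assert back.names == scheme.names
        for name, sites, _ in scheme.subsets:
            assert back.sites(name) == sites

    def test_nexus_parses_with_independent_reader(self, tmp_path, scheme):
        # Bio.Nexus resolves charsets only in the context of a data block,
        # so embed the sets block after a dummy matrix of the right length
        import io

        from Bio.Nexus.Nexus import Nexus

        out = tmp_path / "scheme.nex"
        write_scheme(scheme, "nexus", out)
        sets_block = out.read_text().split("\n", 1)[1]
        n = scheme.total_sites
        data = (
            "#NEXUS\nbegin data;\n"
            f"dimensions ntax=2 nchar={n};\n"
            "format datatype=dna missing=? gap=-;\n"
            f"matrix\na {'A' * n}\nb {'A' * n}\n;\nend;\n"
        )
        nex = Nexus(io.StringIO(data + sets_block))
        # Bio.Nexus stores charset positions 0-based
        for name, sites, _ in scheme.subsets:
            assert sorted(nex.charsets[name]) == [s - 1 for s in sites]

    def test_unsupported_format(self, tmp_path, scheme):
        with pytest.raises(ValueError):
            write_scheme(scheme, "phyml", tmp_path / "x")
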