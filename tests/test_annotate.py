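import itertools

import numpy as np
import pytest

from surfann import examples as ex
from surfann.annotate import (
    IonLadder,
    annotate_spectrum,
    assign_terminal_residue,
    build_spectrum_graph,
    classify_family,
    extract_ladder,
    infer_lipid_anchor,
    reconcile_complements,
)
from surfann.config import load_templates
from surfann.exceptions import DomainError, InconsistencyError
from surfann.masses import LipidSeries, PROTON_MASS
from surfann.simulate import generate_theoretical_spectrum, place_decoys
from surfann.spectra import Peak, Spectrum

from _oracles import brute_longest_path


def _spec(mzs, precursor=None, intensities=None):
    intensities = intensities or [100.0] * len(mzs)
    return Spectrum(
        peaks=tuple(Peak(m, i) for m, i in zip(mzs, intensities)),
        ms_level=2 if precursor else 1,
        precursor_mz=precursor,
    )


class TestSpectrumGraph:
    def test_printed_c13_b_rungs_form_a_path(self, table):
        g = build_spectrum_graph(
            _spec(ex.C13_B_LADDER, precursor=ex.C13_PRECURSOR), tol=1.6, table=table
        )
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == 5
        assert all(g.has_edge(u, v) for u, v in zip(ex.C13_B_LADDER, ex.C13_B_LADDER[1:]))

    def test_no_edge_for_non_residue_gap(self, table):
        g = build_spectrum_graph(_spec((400.0, 450.0), precursor=900.0), tol=0.8, table=table)
        assert g.number_of_edges() == 0

    def test_precursor_and_dehydration_peaks_excluded(self, table):
        g = build_spectrum_graph(ex.c13_spectrum(), tol=1.6, table=table)
        assert ex.C13_PRECURSOR not in g.nodes  # molecular-ion reading removed
        g12 = build_spectrum_graph(ex.c12_spectrum(), tol=1.6, table=table)
        assert ex.C12_WATER_LOSS not in g12.nodes

    def test_edges_match_all_pairs_oracle(self, table, rng):
        for _ in range(50):
            mzs = sorted(rng.uniform(200, 1000, size=12))
            g = build_spectrum_graph(_spec(mzs, precursor=1500.0), tol=0.8, table=table)
            want = {
                (u, v)
                for u, v in itertools.combinations(mzs, 2)
                if table.match(v - u, 0.8)
            }
            assert set(g.edges) == want


class TestExtractLadder:
    def test_printed_c12_b_rungs_with_decoys(self, table, rng):
        decoys = place_decoys(
            list(ex.C12_B_LADDER) + [ex.C12_PRECURSOR], 20, (150.0, 960.0), 2.0, rng
        )
        spectrum = _spec(
            sorted(ex.C12_B_LADDER + tuple(decoys)), precursor=ex.C12_PRECURSOR
        )
        ladder = extract_ladder(build_spectrum_graph(spectrum, tol=1.6, table=table))
        assert ladder.rungs == ex.C12_B_LADDER

    def test_empty_graph_gives_empty_ladder(self, table):
        g = build_spectrum_graph(_spec((300.0, 350.0), precursor=900.0), 0.8, table)
        assert len(extract_ladder(g)) == 0

    def test_matches_exhaustive_path_enumeration(self, table, rng):
        for trial in range(120):
            n = int(rng.integers(3, 13))
            # mix residue-like gaps and junk so graphs have real structure
            mzs = [float(rng.uniform(200, 300))]
            for _ in range(n - 1):
                step = float(rng.choice([99.07, 113.08, 115.03, 128.09, 60.0, 45.0]))
                mzs.append(mzs[-1] + step + float(rng.normal(0, 0.3)))
            intensities = list(rng.uniform(1, 100, size=len(mzs)))
            spectrum = _spec(sorted(mzs), precursor=max(mzs) + 500, intensities=intensities)
            g = build_spectrum_graph(spectrum, tol=0.8, table=table)
            got = extract_ladder(g).rungs
            want = brute_longest_path(
                {m: g.nodes[m]["intensity"] for m in g.nodes}, set(g.edges)
            )
            assert got == want, f"trial {trial}"


class TestTerminalResidue:
    @pytest.mark.parametrize(
        "precursor,top,delta,symbol",
        [
            (994.0, 881.66, 112.34, "Leu/Ile"),
            (1007.65, 894.17, 113.48, "Leu/Ile"),
        ],
    )
    def test_printed_ring_closing_residue(self, table, precursor, top, delta, symbol):
        ladder = IonLadder("b", rungs=(top,))
        got = assign_terminal_residue(precursor, ladder, tol=0.8, table=table)
        assert got.delta == pytest.approx(delta, abs=1e-6)
        assert got.candidates[0].symbol == symbol

    def test_tiny_delta_has_no_candidates(self, table):
        got = assign_terminal_residue(994.0, IonLadder("b", rungs=(990.0,)), 0.8, table)
        assert got.delta == pytest.approx(4.0)
        assert got.candidates == ()

    def test_empty_ladder_is_a_precondition_error(self, table):
        with pytest.raises(DomainError):
            assign_terminal_residue(994.0, IonLadder(None), 0.8, table)


class TestLipidAnchor:
    def test_c12_anchor_from_first_printed_rung(self, table):
        ladder = IonLadder("b", rungs=(441.05,))
        got = infer_lipid_anchor(ladder, ("Glu", "Leu/Ile"), 1.2, table)
        assert got is not None
        assert got.n == 12
        assert got.error == pytest.approx(-0.246, abs=1e-3)

    def test_c13_anchor_matches_brute_force_over_series(self, table):
        ladder = IonLadder("b", rungs=(341.03,))
        got = infer_lipid_anchor(ladder, ("Glu",), 1.2, table)
        series = LipidSeries()
        residual = 341.03 - PROTON_MASS - table.mass("Glu")
        best_n = min(
            range(series.n_min, series.n_max + 1),
            key=lambda n: abs(residual - series.lipid_mass(n)),
        )
        assert got is not None and got.n == best_n == 13
        assert got.error == pytest.approx(residual - series.lipid_mass(13), abs=1e-9)

    def test_negative_residual_is_inconsistent(self, table):
        with pytest.raises(InconsistencyError):
            infer_lipid_anchor(IonLadder("b", rungs=(120.0,)), ("Glu",), 1.2, table)


class TestComplements:
    def test_printed_c12_pairs(self):
        b = IonLadder("b", rungs=ex.C12_B_LADDER)
        y = IonLadder("y", rungs=ex.C12_Y_LADDER)
        pairs = reconcile_complements(994.0, b, y, comp_tol=1.2)
        by = {(p.b_mz, p.y_mz): p.sum_error for p in pairs}
        assert by[(441.05, 553.99)] == pytest.approx(1.04, abs=1e-6)
        assert by[(653.36, 341.13)] == pytest.approx(0.49, abs=1e-6)
        # 440.01 = 994 - 553.99, the published complement reading
        assert 994.0 - 553.99 == pytest.approx(440.01, abs=1e-6)

    def test_unmatched_y_rung_yields_no_pair(self):
        b = IonLadder("b", rungs=(441.05,))
        y = IonLadder("y", rungs=(341.13,))
        assert reconcile_complements(994.0, b, y, comp_tol=1.2) == []

    def test_every_pair_satisfies_tolerance(self, rng):
        for _ in range(30):
            b = IonLadder("b", rungs=tuple(sorted(rng.uniform(300, 900, size=5))))
            y = IonLadder("y", rungs=tuple(sorted(rng.uniform(100, 700, size=4))))
            for p in reconcile_complements(1000.0, b, y, comp_tol=1.2):
                assert abs(p.b_mz + p.y_mz - 1000.0) <= 1.2


class TestClassifyFamily:
    C12_SETS = [
        ("Glu",),
        ("Leu/Ile",),
        ("Leu/Ile",),
        ("Val",),
        ("Asp",),
        ("Leu/Ile",),
        ("Leu/Ile",),
    ]

    def test_c12_candidate_sets_classify_as_surfactin(self):
        call = classify_family(self.C12_SETS, 12, load_templates())
        assert call.family == "surfactin"
        assert call.matched_positions == 7

    def test_wrong_position_five_is_reported(self):
        sets = list(self.C12_SETS)
        sets[4] = ("Val",)
        call = classify_family(sets, 12, load_templates())
        assert call.family == "unassigned"
        assert any("position 5" in f for f in call.failures)

    def test_ambiguous_position_still_matches_and_is_flagged(self):
        sets = list(self.C12_SETS)
        sets[5] = ("Asn", "Leu/Ile")
        call = classify_family(sets, 12, load_templates())
        assert call.family == "surfactin"
        assert 6 in call.ambiguous_positions

    def test_chain_length_outside_template_range(self):
        call = classify_family(self.C12_SETS, 25, load_templates())
        assert call.family == "unassigned"

    def test_incomplete_stub_templates_never_match(self):
        sets = [("Asn",)] + [("Leu/Ile",)] * 6
        call = classify_family(sets, 14, load_templates())
        assert call.family == "unassigned"  # iturin stub is skipped


class TestAnnotateSpectrum:
    def test_printed_c12_with_decoys(self, nominal_cfg):
        a = annotate_spectrum(ex.c12_spectrum(n_decoys=20, seed=5), nominal_cfg)
        assert a.family == "surfactin"
        assert a.chain_length == 12
        assert a.b_ladder.rungs == ex.C12_B_LADDER
        assert a.y_ladder.rungs == ex.C12_Y_LADDER
        assert a.terminal.delta == pytest.approx(112.34, abs=1e-6)
        assert a.terminal.candidates[0].symbol == "Leu/Ile"
        assert [s[0] for s in a.sequence] == [
            "Glu", "Leu/Ile", "Leu/Ile", "Val", "Asp", "Leu/Ile", "Leu/Ile",
        ]
        assert a.water_loss["precursor"].mz == 976.53
        assert a.assumed_positions == (1, 2)

    def test_printed_c13_with_decoys(self, nominal_cfg):
        a = annotate_spectrum(ex.c13_spectrum(n_decoys=20, seed=5), nominal_cfg)
        assert a.family == "surfactin"
        assert a.chain_length == 13
        assert a.b_ladder.rungs == ex.C13_B_LADDER
        assert a.terminal.delta == pytest.approx(113.48, abs=1e-6)
        assert a.water_loss["top_rung"].mz == 876.17

    def test_pure_noise_is_unassigned(self, default_cfg, rng):
        decoys = place_decoys([500.0], 15, (150.0, 900.0), 2.0, rng)
        a = annotate_spectrum(_spec(sorted(decoys), precursor=994.0), default_cfg)
        assert a.family == "unassigned"
        assert len(a.b_ladder) == 0 and len(a.y_ladder) == 0

    @pytest.mark.parametrize("n", range(10, 18))
    def test_noiseless_round_trip_recovers_template_and_n(self, default_cfg, n):
        tpl = load_templates()["surfactin"]
        _, ms2 = generate_theoretical_spectrum(tpl, n)
        a = annotate_spectrum(ms2, default_cfg)
        assert a.family == "surfactin"
        assert a.chain_length == n
        assert all(e < 1e-6 for e in a.b_ladder.step_errors)
        assert abs(a.lipid_error) < 1e-6

    @pytest.mark.parametrize("cfg_name", ["default_cfg", "nominal_cfg"])
    def test_exclusion_respecting_decoys_never_change_the_call(
        self, request, cfg_name, rng
    ):
        cfg = request.getfixturevalue(cfg_name)
        tpl = load_templates()["surfactin"]
        _, clean = generate_theoretical_spectrum(tpl, 14)
        base = annotate_spectrum(clean, cfg)
        decoys = place_decoys(
            list(clean.mzs) + [clean.precursor_mz], 20, (150.0, 950.0), 2.0, rng
        )
        noisy = Spectrum(
            peaks=clean.peaks + tuple(Peak(d, 10.0) for d in decoys),
            ms_level=2,
            precursor_mz=clean.precursor_mz,
        )
        got = annotate_spectrum(noisy, cfg)
        assert got.family == base.family
        assert got.chain_length == base.chain_length
        assert got.b_ladder.rungs == base.b_ladder.rungs
        assert got.y_ladder.rungs == base.y_ladder.rungs
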