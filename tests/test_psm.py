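"""PSM filter cascade: dedup, acidic consensus, site collapse, reconciliation."""

import numpy as np
import pytest

from sulfoscan import (
    PSMRecord,
    SimParams,
    classify,
    default_panel,
    neutral_loss_report,
    parse_peptide,
    simulate_run,
)
from sulfoscan.psm import (
    acidic_consensus_filter,
    cascade,
    charge_state_distribution,
    collapse_unique_sites,
    dedupe_scans,
    has_acidic_consensus,
    read_psm_tsv,
    reconcile_with_nl,
    rt_shift,
    sites_to_frame,
)


def psm(scan=1, pep="EDFED[sY]EFDGK", score=40.0, ppm=0.5, protein="P1", **kw):
    return PSMRecord(
        scan_id=scan,
        peptide=parse_peptide(pep),
        protein=protein,
        score=score,
        ppm_error=ppm,
        **kw,
    )


class TestDedupeScans:
    def test_highest_score_survives(self):
        out = dedupe_scans([psm(scan=1, score=40.0), psm(scan=1, score=35.0)])
        assert len(out) == 1 and out[0].score == 40.0

    def test_unique_scans_unchanged(self):
        records = [psm(scan=i) for i in range(1, 4)]
        assert dedupe_scans(records) == records

    def test_ppm_tiebreak(self):
        a = psm(scan=1, score=40.0, ppm=1.2)
        b = psm(scan=1, score=40.0, ppm=0.3)
        assert dedupe_scans([a, b]) == [b]

    def test_idempotent(self):
        records = [psm(scan=1, score=40.0), psm(scan=1, score=35.0), psm(scan=2)]
        once = dedupe_scans(records)
        assert dedupe_scans(once) == once


class TestAcidicConsensus:
    @pytest.mark.parametrize(
        "pep,kept",
        [
            ("EDFED[sY]EFDGK", True),    # D at -1, E at +1
            ("AAAA[sY]AAAA", False),     # no acidic neighbor
            ("[sY]DPEEK", True),         # N-terminal site, D at +1
            ("AAAK[sY]", False),         # C-terminal site, K at -1
            ("AAAE[sY]", True),          # C-terminal site, E at -1
        ],
    )
    def test_rule(self, pep, kept):
        out = acidic_consensus_filter([psm(pep=pep)])
        assert bool(out) == kept

    def test_no_modified_tyr_dropped(self):
        out = acidic_consensus_filter([psm(pep="EDFEDYEFDGK")])
        assert out == []

    def test_idempotent(self):
        records = [psm(pep="EDFED[sY]EFDGK"), psm(scan=2, pep="AAAA[sY]AAAA")]
        once = acidic_consensus_filter(records)
        assert acidic_consensus_filter(once) == once

    def test_neighbor_helper_at_edges(self):
        p = parse_peptide("[sY]DPEEK")
        assert has_acidic_consensus(p, 1)


class TestCollapseUniqueSites:
    def test_three_psms_one_site(self):
        records = [psm(scan=i, score=30.0 + i) for i in (1, 2, 3)]
        sites = collapse_unique_sites(records)
        assert len(sites) == 1
        assert sites[0].n_psms == 3
        assert sites[0].best_psm.score == 33.0

    def test_two_positions_two_sites(self):
        records = [
            psm(scan=1, pep="SYD[sY]MEGEDIR"),
            psm(scan=2, pep="S[sY]DYMEGEDIR"),
        ]
        assert len(collapse_unique_sites(records)) == 2

    def test_oxidation_variant_merges(self):
        records = [
            psm(scan=1, pep="D[sY]MGWMDFGR"),
            psm(scan=2, pep="D[sY]M[ox]GWMDFGR"),
        ]
        sites = collapse_unique_sites(records)
        assert len(sites) == 1 and sites[0].n_psms == 2

    def test_protein_coordinates_when_fasta_given(self):
        proteins = {"P1": "MAAEDFEDYEFDGKLL"}
        sites = collapse_unique_sites([psm()], proteins)
        assert sites[0].position == 9  # Y at protein position 9
        assert sites[0].site_key == ("P1", 9)

    def test_peptide_not_in_protein_falls_back(self):
        proteins = {"P1": "MKKKKK"}
        sites = collapse_unique_sites([psm()], proteins)
        assert sites[0].site_key == ("EDFEDYEFDGK", 6)

    def test_collapse_idempotent_by_construction(self):
        records = [psm(scan=1), psm(scan=2)]
        a = collapse_unique_sites(records)
        b = collapse_unique_sites([a[0].best_psm])
        assert a[0].site_key == b[0].site_key

    def test_empty_input(self):
        assert collapse_unique_sites([]) == []


def _classification_for(pep, seed=5):
    params = SimParams(seed=seed)
    from sulfoscan import simulate_low_nce_scan

    s = simulate_low_nce_scan(parse_peptide(pep), 2, params, params.rng())
    return classify(neutral_loss_report(s))


class TestReconcileWithNL:
    def test_phospho_recalled_sulfated(self):
        # search annotated phospho, but the linked survey scan shows -80 loss
        sites = collapse_unique_sites([psm(scan=2, pep="EDFED[pY]EFDGK")])
        cls = {1: _classification_for("EDFED[sY]EFDGK")}
        out = reconcile_with_nl(sites, cls, links={2: 1})
        assert out[0].mod_name == "sulfo"
        assert any("re-called" in f for f in out[0].flags)

    def test_agreement_unchanged(self):
        sites = collapse_unique_sites([psm(scan=2)])
        cls = {1: _classification_for("EDFED[sY]EFDGK")}
        out = reconcile_with_nl(sites, cls, links={2: 1})
        assert out[0].mod_name == "sulfo" and not any("re-called" in f for f in out[0].flags)

    def test_second_site_review_flag(self):
        sites = collapse_unique_sites([psm(scan=2)])
        cls = {1: _classification_for("SGD[sY]ED[sY]SPK")}
        assert cls[1].n_sites_estimate == 2
        out = reconcile_with_nl(sites, cls, links={2: 1})
        assert any("second-site" in f for f in out[0].flags)

    def test_missing_linkage_leaves_call(self):
        sites = collapse_unique_sites([psm(scan=2)])
        out = reconcile_with_nl(sites, {}, links={})
        assert out[0].nl_evidence is None and out[0].mod_name == "sulfo"


class TestChargeStateDistribution:
    def test_single_charge_all_mass_there(self):
        groups = {"sY": [psm(scan=i, precursor_z=2) for i in range(3)]}
        table = charge_state_distribution(groups)
        assert table.loc["sY", 2] == 1.0

    def test_fractions_sum_to_one(self):
        groups = {
            "sY": [psm(scan=1, precursor_z=2, intensity=90.0),
                   psm(scan=2, precursor_z=3, intensity=10.0)],
            "pY": [psm(scan=3, precursor_z=2, intensity=50.0),
                   psm(scan=4, precursor_z=3, intensity=50.0)],
        }
        table = charge_state_distribution(groups)
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-9)
        assert table.loc["sY", 2] == pytest.approx(0.9)

    def test_count_weighting(self):
        groups = {"g": [psm(scan=1, precursor_z=2), psm(scan=2, precursor_z=3)]}
        table = charge_state_distribution(groups, weight="count")
        assert table.loc["g", 2] == pytest.approx(0.5)


class TestRtShift:
    def test_identical_rts_zero_shift(self):
        records = [psm(scan=1, pep="EDFEDYEFDGK", rt=300.0), psm(scan=2, rt=300.0)]
        table = rt_shift(records)
        assert table.iloc[0]["rt_shift_s"] == 0.0

    def test_replicate_shift_and_se(self):
        records = [psm(scan=1, pep="EDFEDYEFDGK", rt=300.0)]
        records += [psm(scan=i + 2, rt=rt) for i, rt in enumerate((300.0, 310.0, 320.0))]
        table = rt_shift(records)
        assert table.iloc[0]["rt_shift_s"] == pytest.approx(10.0)
        assert table.iloc[0]["se_s"] == pytest.approx(10.0 / 3 ** 0.5)

    def test_missing_counterpart_skipped(self):
        table = rt_shift([psm(scan=1, rt=300.0)])
        assert table.empty


class TestCascade:
    def _toy_table(self):
        records = [psm(scan=i, pep="AGLK", score=10.0) for i in range(1, 7)]  # 6 unmodified
        records += [
            psm(scan=7, pep="EDFED[sY]EFDGK", score=40.0),
            psm(scan=7, pep="EDFED[pY]EFDGK", score=35.0),   # duplicate scan
            psm(scan=8, pep="AAAA[sY]AAAA", score=30.0),      # fails consensus
            psm(scan=9, pep="SYD[sY]MEGEDIR", score=45.0),
        ]
        return records

    def test_funnel_counts(self):
        sites, funnel = cascade(self._toy_table())
        assert list(funnel["count"]) == [10, 4, 3, 2, 2]

    def test_funnel_monotone(self):
        counts = cascade(self._toy_table())[1]["count"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_empty_input_all_zero(self):
        sites, funnel = cascade([])
        assert (funnel["count"] == 0).all() and sites == []

    def test_cascade_deterministic(self):
        a = cascade(self._toy_table())[1]
        b = cascade(self._toy_table())[1]
        assert a.equals(b)


class TestEndToEnd:
    def test_simulated_panel_recovery(self, sim_run):
        """Every ground-truth sY site survives the cascade and no
        phosphopeptide ends up called sulfated after NL reconciliation."""
        run, truth = sim_run
        scans = run.by_scan()
        # loss-triggered acquisition: an identification scan exists only
        # when the survey scan fired the trigger
        from sulfoscan import trigger

        acquired = [t for t in truth if trigger(scans[t.low_nce_scan]).triggered]
        assert {t.true_mod for t in acquired} == {"sulfo"}
        # emulate a search-engine export: the near-isobaric pair is often
        # mis-annotated, so report every modified peptide as phospho
        records = []
        for t in acquired:
            pep_text = str(t.peptide).replace("[sY]", "[pY]")
            records.append(
                PSMRecord(
                    scan_id=t.high_nce_scan,
                    peptide=parse_peptide(pep_text),
                    protein="SIM",
                    score=50.0,
                    precursor_z=t.charge,
                )
            )
        cls = {
            t.low_nce_scan: classify(neutral_loss_report(scans[t.low_nce_scan]))
            for t in truth
        }
        links = {t.high_nce_scan: t.low_nce_scan for t in truth}
        sites, funnel = cascade(records, classifications=cls, links=links)

        truth_sy_sites = {
            (t.peptide.sequence, pos)
            for t in truth
            if t.true_mod == "sulfo"
            for pos in t.true_sites
        }
        called_sulfo = {s.site_key for s in sites if s.mod_name == "sulfo"}
        assert truth_sy_sites <= called_sulfo
        # every reported site traces back to a true sulfopeptide scan:
        # no phosphopeptide contributed an identification at all
        truth_by_ident_scan = {t.high_nce_scan: t for t in truth}
        for s in sites:
            assert truth_by_ident_scan[s.best_psm.scan_id].true_mod == "sulfo"


def test_psm_tsv_round_trip(tmp_path):
    path = tmp_path / "psms.tsv"
    path.write_text(
        "scan\tpeptide\tprotein\tscore\tppm_error\tz\trt\textra\n"
        "1\tEDFED[sY]EFDGK\tP1\t42.5\t-0.8\t2\t310.5\tignored\n"
        "2\tAGLK\tP2\t10.0\t0.1\t2\t100.0\tignored\n"
    )
    records = read_psm_tsv(path)
    assert len(records) == 2
    assert records[0].score == 42.5
    assert records[0].peptide.mod_positions("sulfo") == (6,)
    frame = sites_to_frame(collapse_unique_sites([records[0]]))
    assert frame.iloc[0]["mod"] == "sulfo"
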