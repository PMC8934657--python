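import numpy as np
import pytest

from conftest import make_ar
from selratio.genomic_io import GenomicInterval, read_bed_intervals
from selratio.neutral_model import (
    AncestralRepeat,
    ArPositionIndex,
    NoNeutralModelError,
    build_local_neutral,
    legacy_local_neutral_1kb,
    select_ancestral_repeats,
)
from selratio.synthetic_data import REPEAT_EXTRA_COLUMNS


def plain_repeat(name, repeat_class, family, divergence, lineage):
    return AncestralRepeat(
        interval=GenomicInterval("chrT", 0, 100, "+", name),
        family=family, repeat_class=repeat_class,
        divergence=divergence, lineage=lineage,
    )


class TestYangSelection:
    @pytest.mark.parametrize(
        "repeat_class,family,divergence,lineage,kept",
        [
            ("SINE/Alu", "AluY", 30.0, "shared", False),       # Alu excluded
            ("LINE/L1", "L1MB7", 22.0, "shared", True),        # L1 > 20 kept
            ("LINE/L1", "L1M4", 19.0, "shared", False),        # L1 <= 20 excluded
            ("DNA/hAT-Charlie", "MER5A", 24.0, "shared", False),  # needs > 25
            ("DNA/hAT-Charlie", "MER20", 25.5, "shared", True),
            ("LINE/L2", "L2a", 26.0, "primate_specific", False),
            ("SINE/MIR", "MIR3", 30.0, "rodent_specific", False),
            ("LINE/L2", "L2b", 25.0, "shared", False),         # boundary: > 25 strict
        ],
    )
    def test_rule_by_rule(self, repeat_class, family, divergence, lineage, kept):
        rec = plain_repeat("r", repeat_class, family, divergence, lineage)
        assert (select_ancestral_repeats([rec]) == [rec]) == kept

    def test_worked_fixture_retains_designed_subset(self, worked_fixtures):
        ivs = read_bed_intervals(worked_fixtures["repeats"], REPEAT_EXTRA_COLUMNS)
        recs = [
            AncestralRepeat(
                interval=iv, family=iv.attributes["family"],
                repeat_class=iv.attributes["repeat_class"],
                divergence=iv.attributes["divergence"],
                lineage=iv.attributes["lineage"],
            )
            for iv in ivs
        ]
        kept = {ar.ar_id for ar in select_ancestral_repeats(recs)}
        assert kept == {"keep_L2", "keep_L1", "keep_hAT"}

    def test_three_species_presence_required(self):
        rec = plain_repeat("r", "LINE/L2", "L2a", 30.0, "shared")
        presence = {"r": {"human", "mouse"}}
        assert select_ancestral_repeats(
            [rec], presence, ("human", "rhesus", "mouse")
        ) == []
        presence = {"r": {"human", "rhesus", "mouse"}}
        assert select_ancestral_repeats(
            [rec], presence, ("human", "rhesus", "mouse")
        ) == [rec]

    def test_missing_divergence_warns_and_skips(self):
        rec = plain_repeat("r", "LINE/L2", "L2a", float("nan"), "shared")
        with pytest.warns(UserWarning):
            assert select_ancestral_repeats([rec]) == []


class TestLocalNeutral:
    def test_two_flanking_ars_give_exactly_1000(self):
        # 600-position AR ending 50 bp upstream, 700-position AR 10 bp downstream
        feature = GenomicInterval("chrT", 2000, 2300, "+", "f")
        up = make_ar("up", "chrT", np.arange(1350, 1950))
        down = make_ar("down", "chrT", np.arange(2310, 3010))
        index = ArPositionIndex([up, down])
        model = build_local_neutral(feature, index, flank=500)
        assert model.complete and model.n_positions == 1000
        assert model.upstream_positions == 500 and model.downstream_positions == 500
        # 3'-most 500 of the upstream AR, 5'-most 500 of the downstream AR
        assert list(model.positions[:500]) == list(np.arange(1450, 1950))
        assert list(model.positions[500:]) == list(np.arange(2310, 2810))

    def test_positions_inside_feature_never_used(self):
        feature = GenomicInterval("chrT", 1000, 1200, "+", "f")
        overlapping = make_ar("o", "chrT", np.arange(900, 1300))
        down = make_ar("d", "chrT", np.arange(1300, 2300))
        index = ArPositionIndex([overlapping, down])
        model = build_local_neutral(feature, index, flank=500)
        inside = (model.positions >= 1000) & (model.positions < 1200)
        assert not inside.any()
        assert model.upstream_positions == 100  # 900..999, then borrow downstream
        assert model.complete and model.n_positions == 1000

    def test_borrow_policy_on_and_off(self):
        feature = GenomicInterval("chrT", 5000, 5100, "+", "f")
        up = make_ar("u", "chrT", np.arange(4700, 5000))     # 300 positions 5'
        down = make_ar("d", "chrT", np.arange(5100, 5900))   # 800 positions 3'
        index = ArPositionIndex([up, down])
        borrowed = build_local_neutral(feature, index, flank=500, borrow=True)
        assert borrowed.n_positions == 1000 and borrowed.complete
        assert borrowed.upstream_positions == 300
        assert borrowed.downstream_positions == 700
        assert borrowed.shortfall_side == "5prime"
        strict = build_local_neutral(feature, index, flank=500, borrow=False)
        assert strict.n_positions == 800 and not strict.complete
        assert strict.upstream_positions == 300 and strict.downstream_positions == 500

    def test_no_positions_anywhere_raises(self):
        index = ArPositionIndex([make_ar("a", "chrOther", np.arange(0, 100))])
        with pytest.raises(NoNeutralModelError):
            build_local_neutral(GenomicInterval("chrT", 100, 200), index)

    def test_excluded_ar_does_not_contribute(self):
        feature = GenomicInterval("chrT", 1000, 1100, "+", "f")
        self_ar = make_ar("self", "chrT", np.arange(1000, 1100))
        other = make_ar("other", "chrT", np.arange(0, 3000))
        index = ArPositionIndex([self_ar, other])
        model = build_local_neutral(feature, index, flank=50, exclude_ar_id="self")
        assert dict(model.contributing_ars) == {"other": 100}

    def test_brute_force_nearest_oracle(self):
        rng = np.random.default_rng(42)
        coords = np.sort(rng.choice(10_000, size=3000, replace=False))
        ar = make_ar("big", "chrT", coords)
        index = ArPositionIndex([ar])
        for start, end, flank in [(4000, 4400, 500), (100, 300, 400), (9000, 9500, 600)]:
            feature = GenomicInterval("chrT", start, end, "+", "f")
            model = build_local_neutral(feature, index, flank=flank, borrow=True)
            # oracle: sort positions by distance to the nearest boundary, per side
            up = sorted([c for c in coords if c < start], key=lambda c: start - c)
            down = sorted([c for c in coords if c >= end], key=lambda c: c - end)
            want_up = up[:flank]
            want_down = down[:flank]
            if len(want_up) < flank:
                want_down = down[: flank + (flank - len(want_up))]
            if len(want_down) < flank:
                want_up = up[: flank + (flank - len(down[:flank]))]
            expected = sorted(want_up) + sorted(want_down)
            assert list(model.positions) == expected

    def test_sequences_follow_positions(self):
        # bases encode coordinate parity so sequence order is checkable
        coords = np.arange(100, 200)
        seq = "".join("AC"[c % 2] for c in coords)
        ar = make_ar("enc", "chrT", coords, seq_ref=seq, seq_other=seq)
        index = ArPositionIndex([ar])
        feature = GenomicInterval("chrT", 150, 160, "+", "f")
        model = build_local_neutral(feature, index, flank=20)
        expect = "".join("AC"[c % 2] for c in model.positions)
        assert model.seq_ref == expect


class TestLegacy1kb:
    def test_single_ar_within_window(self):
        feature = GenomicInterval("chrT", 2000, 2100, "+", "f")
        ar = make_ar("a", "chrT", np.arange(1500, 1700))
        model = legacy_local_neutral_1kb(feature, ArPositionIndex([ar]))
        assert model.n_positions == 200

    def test_no_ar_within_window_raises(self):
        feature = GenomicInterval("chrT", 5000, 5100, "+", "f")
        ar = make_ar("a", "chrT", np.arange(100, 300))
        with pytest.raises(NoNeutralModelError):
            legacy_local_neutral_1kb(feature, ArPositionIndex([ar]))

    def test_includes_all_eligible_positions_within_1kb(self):
        # same layout as the 1000-position example: the legacy variant takes
        # every position within 1 kb, exceeding or undershooting 1000
        feature = GenomicInterval("chrT", 2000, 2300, "+", "f")
        up = make_ar("up", "chrT", np.arange(1350, 1950))
        down = make_ar("down", "chrT", np.arange(2310, 3010))
        index = ArPositionIndex([up, down])
        model = legacy_local_neutral_1kb(feature, index)
        # upstream: positions in [1000, 2000) -> all 600; downstream: [2300, 3300) -> all 700
        assert model.upstream_positions == 600
        assert model.downstream_positions == 700
        assert model.n_positions == 1300
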