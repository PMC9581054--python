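"""Edgotype classification rules, enrichment, validation, property changes."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from edgotype import classify as cl
from edgotype.errors import (
    DegenerateTableError,
    IncompleteGeometryError,
    MissingDdgError,
    NoOverlapError,
    ParseError,
)
from edgotype.labels import (
    BURIED,
    EDGETIC,
    EXPOSED,
    INTERFACIAL,
    NONPATHOGENIC,
    PATHOGENIC,
    QUASI_NULL,
    QUASI_WILDTYPE,
)

KEY = ("P1", 10, "A", "V")


def brec(ddg, partner="P2"):
    return cl.DdgRecord("P1", 10, "A", "V", "binding", ddg, partner)


def frec(ddg):
    return cl.DdgRecord("P1", 10, "A", "V", "folding", ddg)


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "pos,iface,rsa,expected",
        [
            (10, {10}, 0.05, INTERFACIAL),  # interface beats burial-range RSA
            (10, set(), 0.30, EXPOSED),
            (10, set(), 0.25, BURIED),  # boundary is buried
            (10, set(), 0.24, BURIED),
        ],
    )
    def test_rules(self, pos, iface, rsa, expected):
        assert cl.classify_location(pos, iface, rsa) == expected

    def test_missing_rsa(self):
        with pytest.raises(IncompleteGeometryError):
            cl.classify_location(10, set(), None)


class TestClassifyEdgotype:
    def test_any_partner_above_cutoff_is_edgetic(self):
        call = cl.classify_edgotype(
            KEY, INTERFACIAL, [brec(0.2, "P2"), brec(0.6, "P3")]
        )
        assert call.edgotype == EDGETIC
        assert call.disrupted_partners == ("P3",)

    def test_interfacial_below_cutoff_is_quasi_wildtype(self):
        call = cl.classify_edgotype(KEY, INTERFACIAL, [brec(0.5), brec(0.1, "P3")])
        assert call.edgotype == QUASI_WILDTYPE  # strict > 0.5

    def test_folding_boundary_inclusive(self):
        assert cl.classify_edgotype(
            KEY, BURIED, folding_record=frec(2.0)
        ).edgotype == QUASI_NULL
        assert cl.classify_edgotype(
            KEY, BURIED, folding_record=frec(1.99)
        ).edgotype == QUASI_WILDTYPE

    def test_exposed_is_quasi_wildtype(self):
        assert cl.classify_edgotype(KEY, EXPOSED).edgotype == QUASI_WILDTYPE

    def test_missing_ddg_errors(self):
        with pytest.raises(MissingDdgError):
            cl.classify_edgotype(KEY, INTERFACIAL, [])
        with pytest.raises(MissingDdgError):
            cl.classify_edgotype(KEY, BURIED)

    def test_partner_order_invariance(self):
        records = [brec(0.7, "P2"), brec(0.9, "P4"), brec(0.1, "P3")]
        calls = {
            cl.classify_edgotype(KEY, INTERFACIAL, perm).disrupted_partners
            for perm in itertools.permutations(records)
        }
        assert calls == {("P2", "P4")}

    def test_raising_binding_cutoff_is_monotone(self):
        """A higher binding cutoff can only demote edgetic calls, never
        create them, and never touches quasi-null calls."""
        records = [brec(0.4, "P2"), brec(0.6, "P3")]
        prev_edgetic = True
        for cutoff in (0.3, 0.5, 0.7):
            call = cl.classify_edgotype(KEY, INTERFACIAL, records,
                                        binding_cutoff=cutoff)
            is_edgetic = call.edgotype == EDGETIC
            assert prev_edgetic or not is_edgetic
            prev_edgetic = is_edgetic
        for cutoff in (0.3, 0.5, 0.7):
            call = cl.classify_edgotype(KEY, BURIED, folding_record=frec(3.0),
                                        binding_cutoff=cutoff)
            assert call.edgotype == QUASI_NULL


class TestParseDdgTable:
    PLAIN = (
        "protein_id\tposition\twt_aa\tmut_aa\tkind\tpartner\tddg\n"
        "P1\t10\tA\tV\tbinding\tP2\t1.25\n"
        "P1\t10\tA\tV\tfolding\t\t0.30\n"
    )
    FOLDX = (
        "Pdb\ttotal energy\n"
        "P1:A10V:P2\t1.25\n"
        "P1:A10V\t0.30\n"
    )

    def test_plain_tsv(self):
        records = cl.parse_ddg_table(self.PLAIN)
        assert len(records) == 2
        assert records[0].kind == "binding" and records[0].partner == "P2"
        assert records[1].kind == "folding" and records[1].partner is None

    def test_foldx_dialect_equals_plain(self):
        assert cl.parse_ddg_table(self.FOLDX) == cl.parse_ddg_table(self.PLAIN)

    def test_empty_file(self):
        assert cl.parse_ddg_table(io.StringIO("")) == []

    def test_unparseable_value_reports_row(self):
        bad = self.PLAIN.replace("1.25", "oops")
        with pytest.raises(ParseError) as exc:
            cl.parse_ddg_table(bad)
        assert exc.value.line == 2


class TestEdgotypeCounts:
    def _calls(self, spec):
        calls, labels = [], {}
        for i, (edgotype, cls) in enumerate(spec):
            key = ("P1", i + 1, "A", "V")
            loc = {EDGETIC: INTERFACIAL, QUASI_NULL: BURIED}.get(
                edgotype, EXPOSED
            )
            partners = ("P2",) if edgotype == EDGETIC else ()
            calls.append(cl.EdgotypeCall(key, loc, edgotype, partners))
            labels[key] = cls
        return calls, labels

    def test_all_quasi_wildtype(self):
        calls, labels = self._calls([(QUASI_WILDTYPE, NONPATHOGENIC)] * 4)
        counts, fractions = cl.edgotype_counts(calls, labels)
        assert fractions.loc[NONPATHOGENIC].tolist() == [1.0, 0.0, 0.0]

    def test_counts_conserved_and_fractions_sum_to_one(self):
        spec = [(QUASI_WILDTYPE, NONPATHOGENIC)] * 5 + \
            [(EDGETIC, PATHOGENIC)] * 2 + [(QUASI_NULL, PATHOGENIC)] * 3
        calls, labels = self._calls(spec)
        counts, fractions = cl.edgotype_counts(calls, labels)
        assert counts.loc[NONPATHOGENIC].sum() == 5
        assert counts.loc[PATHOGENIC].sum() == 5
        assert fractions.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])


def fisher_two_sided_enumeration(table):
    """Exhaustive two-sided Fisher p: sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(col1, x, exact=True)
                * comb(n - col1, row1 - x, exact=True)
                / comb(n, row1, exact=True))

    p_obs = prob(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(p for x in range(lo, hi + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


class TestEnrichment:
    def _counts(self, qw_n, e_n, qn_n, qw_m, e_m, qn_m):
        return pd.DataFrame(
            [[qw_n, e_n, qn_n], [qw_m, e_m, qn_m]],
            index=[NONPATHOGENIC, PATHOGENIC],
            columns=[QUASI_WILDTYPE, EDGETIC, QUASI_NULL],
        )

    def test_no_association(self):
        _, p = cl.enrichment_test(self._counts(10, 5, 5, 10, 5, 5))
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        _, p = cl.enrichment_test(self._counts(50, 0, 0, 0, 25, 25))
        assert p < 1e-10

    def test_zero_margin(self):
        with pytest.raises(DegenerateTableError):
            cl.enrichment_test(self._counts(0, 5, 5, 0, 5, 5))

    @pytest.mark.parametrize(
        "table", [[[3, 7], [5, 2]], [[10, 2], [4, 9]], [[1, 14], [13, 2]],
                  [[8, 8], [8, 8]], [[0, 12], [9, 3]]]
    )
    def test_matches_exhaustive_enumeration(self, table):
        _, p_scipy = stats.fisher_exact(table, alternative="two-sided")
        assert p_scipy == pytest.approx(
            fisher_two_sided_enumeration(table), rel=1e-9
        )


class TestEvaluateAgainstExperiment:
    def test_perfect_predictions(self):
        truth = {("P", i, "A", "V"): e for i, e in enumerate(
            [EDGETIC] * 3 + [QUASI_NULL] * 3 + [QUASI_WILDTYPE] * 4)}
        df = cl.evaluate_against_experiment(truth, truth).set_index("edgotype")
        assert df.loc[EDGETIC].tpr == 1.0 and df.loc[EDGETIC].fpr == 0.0
        assert df.loc[QUASI_NULL].tpr == 1.0 and df.loc[QUASI_NULL].fpr == 0.0

    def test_hand_built_confusion_fixture(self):
        # 10 mutations: experiment says 4 edgetic, 6 not; predictions hit
        # 2 of the 4 and falsely call 1 of the 6.
        exp, pred = {}, {}
        for i in range(10):
            key = ("P", i, "A", "V")
            exp[key] = EDGETIC if i < 4 else QUASI_WILDTYPE
            pred[key] = EDGETIC if i in (0, 1, 4) else QUASI_WILDTYPE
        df = cl.evaluate_against_experiment(pred, exp).set_index("edgotype")
        assert df.loc[EDGETIC].tpr == pytest.approx(2 / 4)
        assert df.loc[EDGETIC].fpr == pytest.approx(1 / 6)

    def test_random_predictions_have_tpr_near_fpr(self):
        rng = np.random.default_rng(5)
        keys = [("P", i, "A", "V") for i in range(4000)]
        exp = {k: EDGETIC if rng.random() < 0.3 else QUASI_WILDTYPE
               for k in keys}
        pred = {k: EDGETIC if rng.random() < 0.3 else QUASI_WILDTYPE
                for k in keys}
        df = cl.evaluate_against_experiment(pred, exp).set_index("edgotype")
        assert abs(df.loc[EDGETIC].tpr - df.loc[EDGETIC].fpr) < 0.05

    def test_empty_overlap(self):
        with pytest.raises(NoOverlapError):
            cl.evaluate_against_experiment(
                {("P", 1, "A", "V"): EDGETIC}, {("Q", 1, "A", "V"): EDGETIC}
            )


class TestPropertyChangeSummary:
    def test_hydrophobicity_and_weight_directions(self):
        records = pd.DataFrame(
            {
                "wt_aa": ["I", "D", "G"], "mut_aa": ["D", "I", "W"],
                "edgotype": [QUASI_NULL, QUASI_NULL, EDGETIC],
            }
        )
        out = cl.property_change_summary(records)
        # I -> D lowers hydrophobicity, D -> I raises it
        assert out.loc[QUASI_NULL].hydrophobicity_decrease == 0.5
        # G -> W raises molecular weight
        assert out.loc[EDGETIC].molecular_weight_increase == 1.0

    def test_identity_property_table_gives_zero(self):
        records = pd.DataFrame(
            {"wt_aa": ["I", "G"], "mut_aa": ["D", "W"],
             "edgotype": [EDGETIC, EDGETIC]}
        )
        flat = {aa: 1.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        out = cl.property_change_summary(records, flat, flat)
        assert out.loc[EDGETIC].hydrophobicity_decrease == 0.0
        assert out.loc[EDGETIC].molecular_weight_increase == 0.0
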