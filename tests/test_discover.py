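"""Column profiles, diagnostic-site calling, subfamily naming, signatures
and genome scanning."""

import numpy as np
import pytest

from alutrack import discover
from alutrack.align import AlignParams, AnchoredElement, anchor_to_consensus
from alutrack.core_io import ConsensusModel, revcomp


def _element(eid, model, mutate=(), insert=None, coverage=None):
    """AnchoredElement built directly from a consensus with edits."""
    L = len(model.sequence)
    first, last = coverage or (1, L)
    states = {p: model.sequence[p - 1] for p in range(first, last + 1)}
    for pos, base in mutate:
        states[pos] = base
    insertions = {}
    if insert:
        pos, bases = insert
        for k, b in enumerate(bases, start=1):
            insertions[(pos, k)] = b
    return AnchoredElement(
        element_id=eid, states=states, insertions=insertions,
        coverage=(first, last), full_length=(first, last) == (1, L),
    )


@pytest.fixture(scope="module")
def model():
    return ConsensusModel("M", "ACGTACGTACTTGCATGCATTGACCAGTTGACGTACGTAC" * 3)


class TestProfileColumns:
    def test_identical_elements_all_consensus(self, model):
        els = [_element(f"e{i}", model) for i in range(10)]
        prof = discover.profile_columns(els, model)
        for pos, counter in prof.counts.items():
            assert counter == {model.sequence[pos - 1]: 10}

    def test_shared_variant_counted(self, model):
        els = [_element(f"e{i}", model) for i in range(6)] + [
            _element(f"m{i}", model, mutate=[(10, "A")]) for i in range(4)
        ]
        prof = discover.profile_columns(els, model)
        assert prof.counts[10][model.sequence[9]] == 6
        assert prof.counts[10]["A"] == 4

    def test_staggered_coverage_varies_denominators(self, model):
        els = [
            _element("a", model, coverage=(1, 80)),
            _element("b", model, coverage=(41, 120)),
            _element("c", model),
        ]
        prof = discover.profile_columns(els, model)
        assert prof.covering[10] == 2   # a and c
        assert prof.covering[60] == 3   # all
        assert prof.covering[100] == 2  # b and c

    def test_needs_two_elements(self, model):
        with pytest.raises(ValueError):
            discover.profile_columns([_element("a", model)], model)


class TestCallDiagnosticSites:
    def test_shared_substitution_found(self, model):
        els = [_element(f"e{i}", model) for i in range(6)] + [
            _element(f"m{i}", model, mutate=[(10, "A")]) for i in range(4)
        ]
        prof = discover.profile_columns(els, model)
        (site,) = discover.call_diagnostic_sites(prof, model)
        assert site.consensus_position == 10
        assert site.shared_state == "A"
        assert site.carrier_count == 4
        assert set(site.carrier_ids) == {f"m{i}" for i in range(4)}

    def test_private_mutation_not_called(self, model):
        els = [_element(f"e{i}", model) for i in range(5)] + [
            _element("m", model, mutate=[(10, "A")])
        ]
        prof = discover.profile_columns(els, model)
        assert discover.call_diagnostic_sites(prof, model) == []

    def test_shared_insertion_found(self, model):
        els = [_element(f"e{i}", model) for i in range(4)] + [
            _element(f"m{i}", model, insert=(20, "T")) for i in range(3)
        ]
        prof = discover.profile_columns(els, model)
        (site,) = discover.call_diagnostic_sites(prof, model)
        assert (site.kind, site.consensus_position, site.shared_state) == (
            "insertion", 20, "T",
        )

    def test_min_carriers_validated(self, model):
        els = [_element(f"e{i}", model) for i in range(4)]
        prof = discover.profile_columns(els, model)
        with pytest.raises(ValueError):
            discover.call_diagnostic_sites(prof, model, min_carriers=1)


class TestAssignSubfamilies:
    """Naming follows the trunk/lineage convention seeded with known
    subfamilies: {259A} -> Yb8a1, {259A, Yb9 site} -> Yb10, plus 200+T ->
    Yb11."""

    @pytest.fixture()
    def yb_like(self, yb_reg):
        model = yb_reg.models["Yb8"]
        els = (
            [_element(f"yb8_{i}", model) for i in range(6)]
            + [_element(f"yb9_{i}", model, mutate=[(174, "G")]) for i in range(5)]
            + [_element(f"a_{i}", model, mutate=[(259, "A")]) for i in range(4)]
            + [
                _element(f"b_{i}", model, mutate=[(174, "G"), (259, "A")])
                for i in range(3)
            ]
            + [
                _element(
                    f"c_{i}", model, mutate=[(174, "G"), (259, "A")],
                    insert=(200, "T"),
                )
                for i in range(2)
            ]
        )
        prof = discover.profile_columns(els, model)
        sites = discover.call_diagnostic_sites(prof, model)
        known = {"Yb9": frozenset({(174, "substitution", "G")})}
        return els, sites, known

    def test_nomenclature(self, yb_like):
        els, sites, known = yb_like
        calls, _v = discover.assign_subfamilies(els, sites, "Yb8", known=known)
        names = {c.name: set(c.members) for c in calls}
        assert set(names) == {"Yb8", "Yb9", "Yb8a1", "Yb10", "Yb11"}
        assert names["Yb8a1"] == {f"a_{i}" for i in range(4)}
        assert names["Yb10"] == {f"b_{i}" for i in range(3)}
        assert names["Yb11"] == {f"c_{i}" for i in range(2)}
        parents = {c.name: c.parent for c in calls}
        assert parents["Yb11"] == "Yb10"
        assert parents["Yb10"] in ("Yb8a1", "Yb9")

    def test_partition(self, yb_like):
        els, sites, known = yb_like
        calls, _v = discover.assign_subfamilies(els, sites, "Yb8", known=known)
        seen = [m for c in calls for m in c.members]
        assert sorted(seen) == sorted(e.element_id for e in els)

    def test_consensus_identical_set_single_call(self, model):
        els = [_element(f"e{i}", model) for i in range(5)]
        calls, _v = discover.assign_subfamilies(els, [], "Tb8")
        (call,) = calls
        assert call.diagnostic_set == frozenset()
        assert len(call.members) == 5

    def test_nesting_violation_flagged(self, yb_reg):
        model = yb_reg.models["Yb8"]
        els = (
            [_element(f"e{i}", model) for i in range(5)]
            + [
                _element(
                    f"ok_{i}", model, mutate=[(174, "G"), (259, "A")],
                    insert=(200, "T"),
                )
                for i in range(9)
            ]
            # carries 200+T without 259A: reverse-mutation/conversion signal
            + [_element("weird", model, mutate=[(174, "G")], insert=(200, "T"))]
        )
        prof = discover.profile_columns(els, model)
        sites = discover.call_diagnostic_sites(prof, model)
        _calls, violations = discover.assign_subfamilies(els, sites, "Yb8")
        assert any(
            v.element_id == "weird"
            and any(m[0] == 259 for m in v.missing)
            for v in violations
        )


class TestSignature:
    def _calls(self, model, els, base="Yb8", known=None):
        prof = discover.profile_columns(els, model)
        sites = discover.call_diagnostic_sites(prof, model)
        calls, _v = discover.assign_subfamilies(els, sites, base, known=known)
        return prof, sites, calls

    def test_substitution_signature_30nt_centered(self, yb_reg):
        model = yb_reg.models["Yb8"]
        els = [_element(f"e{i}", model) for i in range(5)] + [
            _element(f"a_{i}", model, mutate=[(259, "A")]) for i in range(4)
        ]
        prof, sites, calls = self._calls(model, els)
        call = next(c for c in calls if c.diagnostic_set)
        sig = discover.build_signature(call, sites, model, prof)
        assert sig.window_length == 30
        assert sig.sequence[sig.diagnostic_offset] == "A"
        # flanks are consensus
        expected = (
            model.sequence[243:258] + "A" + model.sequence[259:273]
        )
        assert sig.sequence == expected

    def test_insertion_signature_24nt(self, yb_reg):
        model = yb_reg.models["Yb8"]
        els = [_element(f"e{i}", model) for i in range(5)] + [
            _element(f"i_{i}", model, insert=(200, "T")) for i in range(3)
        ]
        prof, sites, calls = self._calls(model, els)
        call = next(c for c in calls if c.diagnostic_set)
        sig = discover.build_signature(call, sites, model, prof)
        assert sig.window_length == 24
        assert sig.sequence[sig.diagnostic_offset] == "T"
        assert "T" + model.sequence[200:206] in sig.sequence

    def test_boundary_clamp_near_consensus_start(self):
        model = ConsensusModel("M", "GCTAGCATGCATCGCATGACTGCATG")
        els = [_element(f"e{i}", model) for i in range(4)] + [
            _element(f"m{i}", model, mutate=[(5, "T")]) for i in range(3)
        ]
        prof = discover.profile_columns(els, model)
        sites = discover.call_diagnostic_sites(prof, model)
        calls, _v = discover.assign_subfamilies(els, sites, "M8")
        call = next(c for c in calls if c.diagnostic_set)
        sig = discover.build_signature(call, sites, model, prof)
        assert sig.diagnostic_offset == 4  # only 4 flanking columns exist left
        assert sig.sequence[4] == "T"

    def test_window_shrinks_from_a_rich_and_unconserved_columns(self, toy_reg):
        model = toy_reg.models["Tb8"]
        els = [_element(f"e{i}", model) for i in range(50)] + [
            # diagnostic near the A-rich linker (ends at col 67)
            _element(f"m{i}", model, mutate=[(72, "A")]) for i in range(4)
        ]
        prof, sites, calls = self._calls(model, els, base="Tb8")
        call = next(c for c in calls if c.diagnostic_set)
        sig = discover.build_signature(call, sites, model, prof)
        assert sig.window_length < 30  # left flank blocked by the linker
        assert sig.sequence[sig.diagnostic_offset] == "A"


class TestScanGenome:
    def _sig(self):
        return discover.Signature(
            sequence="ACGTAGGCTTACAGATCAGGCATGCAATGG",
            diagnostic_offset=13,
            window_length=30,
            subfamily="S",
        )

    def _background(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def test_planted_occurrences_found(self):
        sig = self._sig()
        bg = self._background()
        genome = {"chr1": bg[:1000] + sig.sequence + bg[1000:2000] + sig.sequence + bg[2000:]}
        hits = discover.scan_genome(genome, sig, max_mismatch=1)
        assert len(hits) == 2
        assert all(h.strand == "+" for h in hits)

    def test_reverse_complement_hit(self):
        sig = self._sig()
        bg = self._background(seed=1)
        genome = {"chr1": bg[:500] + revcomp(sig.sequence) + bg[500:]}
        (hit,) = discover.scan_genome(genome, sig, max_mismatch=1)
        assert hit.strand == "-"
        assert hit.start == 500

    def test_diagnostic_reversion_rejected_within_budget(self):
        sig = self._sig()
        reverted = list(sig.sequence)
        reverted[sig.diagnostic_offset] = "C"  # flanks perfect, diagnostic off
        bg = self._background(seed=2)
        genome = {"chr1": bg[:700] + "".join(reverted) + bg[700:]}
        assert discover.scan_genome(genome, sig, max_mismatch=1) == []

    def test_one_mismatch_tolerated_elsewhere(self):
        sig = self._sig()
        near = list(sig.sequence)
        near[2] = "T" if near[2] != "T" else "A"
        bg = self._background(seed=3)
        genome = {"chr1": bg[:800] + "".join(near) + bg[800:]}
        assert len(discover.scan_genome(genome, sig, max_mismatch=1)) == 1
        assert discover.scan_genome(genome, sig, max_mismatch=0) == []

    def test_zero_mismatch_equals_naive_search(self):
        sig = self._sig()
        rng = np.random.default_rng(4)
        # low-complexity background makes chance hits plausible
        bg = "".join("AC"[i] for i in rng.integers(0, 2, 20000))
        genome = {"chr1": bg[:900] + sig.sequence + bg[900:]}
        hits = discover.scan_genome(genome, sig, max_mismatch=0)
        seq = genome["chr1"]
        naive = set()
        for pat, strand in ((sig.sequence, "+"), (revcomp(sig.sequence), "-")):
            start = seq.find(pat)
            while start != -1:
                naive.add((start, strand))
                start = seq.find(pat, start + 1)
        assert {(h.start, h.strand) for h in hits} == naive

    def test_excessive_mismatch_budget_rejected(self):
        with pytest.raises(ValueError):
            discover.scan_genome({"c": "ACGT" * 100}, self._sig(), max_mismatch=9)
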