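"""Polymorphism detection, binning and parent-of-origin calling."""

from collections import Counter

import pandas as pd
import pytest

from imprintscan import (
    AlleleCallTable,
    CrossDesign,
    Sample,
    SimulationConfig,
    build_allele_table,
    call_all,
    call_parent_of_origin,
    detect_polymorphic,
    simulate_allele_table,
    simulate_transcriptome,
)

A, B = "Col-0", "Ler-0"
TIMEPOINTS = (3, 4, 5)


def _design(missing: set[str] = frozenset()) -> CrossDesign:
    samples = {}
    for tp in TIMEPOINTS:
        for mother, father in ((A, A), (B, B), (A, B), (B, A)):
            label = f"{mother}x{father}_{tp}"
            if label not in missing:
                samples[label] = Sample(mother, father, tp)
    return CrossDesign((A, B), samples, TIMEPOINTS)


def _table(rows: dict) -> AlleleCallTable:
    """rows: key -> {sample: 0/1}; absent samples default to 0."""
    design = _design()
    frame = pd.DataFrame.from_dict(
        {key: {label: cells.get(label, 0) for label in design.samples}
         for key, cells in rows.items()},
        orient="index",
    )
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["primer_key", "bin_center"])
    return AlleleCallTable(frame)


def _cells(self_acc=None, f1_mother_carrier=(), f1_mother_other=(), both_selfs=False):
    cells = {}
    selfs = (A, B) if both_selfs else ((self_acc,) if self_acc else ())
    for acc in selfs:
        for tp in TIMEPOINTS:
            cells[f"{acc}x{acc}_{tp}"] = 1
    carrier = self_acc or A
    other = B if carrier == A else A
    for tp in f1_mother_carrier:
        cells[f"{carrier}x{other}_{tp}"] = 1
    for tp in f1_mother_other:
        cells[f"{other}x{carrier}_{tp}"] = 1
    return cells


KEY = ("BstYI+TCC / MseI+AG", 137.0)


def test_detect_polymorphic_carrier_assignment():
    table = _table({
        KEY: _cells(self_acc=A),
        ("k2", 88.0): _cells(both_selfs=True),
        ("k3", 99.0): {},
    })
    carriers = detect_polymorphic(table, _design())
    assert carriers == {KEY: A}


def test_detect_polymorphic_requires_consistency():
    cells = _cells(self_acc=B)
    del cells[f"{B}x{B}_4"]  # present at 2 of 3 timepoints only
    carriers = detect_polymorphic(_table({KEY: cells}), _design())
    assert KEY not in carriers


def test_missing_self_sample_is_an_error():
    design = _design(missing={f"{B}x{B}_4"})
    with pytest.raises(ValueError, match=r"Ler-0 x Ler-0.*4"):
        detect_polymorphic(_table({KEY: _cells(self_acc=A)}), design)


def test_maternal_call_with_supporting_timepoints():
    table = _table({KEY: _cells(self_acc=A, f1_mother_carrier=(3, 4))})
    call = call_parent_of_origin(KEY, table, _design())
    assert call.call == "maternal"
    assert call.carrier_accession == A
    assert call.supporting_timepoints == (3, 4)


def test_paternal_mirror():
    table = _table({KEY: _cells(self_acc=A, f1_mother_other=(3, 5))})
    call = call_parent_of_origin(KEY, table, _design())
    assert call.call == "paternal"
    assert call.supporting_timepoints == (3, 5)


def test_biallelic_pattern_is_not_uniparental():
    table = _table({
        KEY: _cells(self_acc=A, f1_mother_carrier=TIMEPOINTS, f1_mother_other=TIMEPOINTS)
    })
    assert call_parent_of_origin(KEY, table, _design()).call == "not_uniparental"


def test_single_stage_support_is_insufficient():
    table = _table({KEY: _cells(self_acc=A, f1_mother_carrier=(4,))})
    call = call_parent_of_origin(KEY, table, _design(), min_stages=2)
    assert call.call == "insufficient_evidence"
    # the same pattern passes a min_stages=1 rule
    assert call_parent_of_origin(KEY, table, _design(), min_stages=1).call == "maternal"


def test_mixed_direction_support_is_not_uniparental():
    table = _table({
        KEY: _cells(self_acc=A, f1_mother_carrier=(3, 4), f1_mother_other=(5,))
    })
    assert call_parent_of_origin(KEY, table, _design()).call == "not_uniparental"


def test_missing_f1_timepoint_is_uninformative():
    design = _design(missing={f"{A}x{B}_5"})
    table_frame_rows = {KEY: _cells(self_acc=A, f1_mother_carrier=(3, 4))}
    design_labels = set(design.samples)
    frame = pd.DataFrame.from_dict(
        {k: {label: v.get(label, 0) for label in design_labels}
         for k, v in table_frame_rows.items()},
        orient="index",
    )
    frame.index = pd.MultiIndex.from_tuples(frame.index)
    call = call_parent_of_origin(KEY, AlleleCallTable(frame), design)
    assert call.call == "maternal" and call.supporting_timepoints == (3, 4)


def test_unknown_carrier_is_a_precondition_error():
    table = _table({KEY: _cells(both_selfs=True)})
    with pytest.raises(ValueError, match="carrier"):
        call_parent_of_origin(KEY, table, _design())


def test_accession_label_symmetry():
    """Swapping accession labels swaps the carrier but never the call."""
    config = SimulationConfig(seed=5, n_genes=30)
    _, _, truth = simulate_transcriptome(config)
    table, design, labels = simulate_allele_table(truth, config)
    calls = {c.key: c for c in call_all(table, design)}

    swap = {A: B, B: A}

    def swap_label(label: str) -> str:
        parents, suffix = label.split("_", 1)
        mother, father = parents.split("x")
        return f"{swap[mother]}x{swap[father]}_{suffix}"

    swapped_samples = {
        swap_label(label): Sample(swap[s.mother], swap[s.father], s.timepoint)
        for label, s in design.samples.items()
    }
    swapped_design = CrossDesign((B, A), swapped_samples, design.timepoints)
    swapped_table = AlleleCallTable(table.calls.rename(columns=swap_label))
    swapped_calls = {c.key: c for c in call_all(swapped_table, swapped_design)}
    assert calls.keys() == swapped_calls.keys()
    for key, call in calls.items():
        assert swapped_calls[key].call == call.call
        if call.carrier_accession is not None:
            assert swapped_calls[key].carrier_accession == swap[call.carrier_accession]


def test_counts_conservation(small_transcriptome, small_config):
    """Every TDF row receives exactly one call category."""
    _, _, truth = small_transcriptome
    table, design, _ = simulate_allele_table(truth, small_config)
    calls = call_all(table, design)
    assert len(calls) == len(table.keys)
    valid = {"maternal", "paternal", "not_uniparental", "not_polymorphic",
             "insufficient_evidence"}
    assert {c.call for c in calls} <= valid


def test_noiseless_recovery_precision_recall(small_transcriptome, small_config):
    _, _, truth = small_transcriptome
    table, design, labels = simulate_allele_table(truth, small_config)
    expected = labels.set_index(["primer_key", "bin_center"]).expected_call
    calls = {c.key: c.call for c in call_all(table, design)}
    assert all(calls[key] == expected_call for key, expected_call in expected.items())


def test_full_dropout_yields_no_parent_calls(small_transcriptome):
    config = SimulationConfig(seed=11, n_genes=40, dropout=1.0)
    _, _, truth = small_transcriptome
    table, design, _ = simulate_allele_table(truth, config)
    counts = Counter(c.call for c in call_all(table, design))
    assert counts["maternal"] == counts["paternal"] == 0


def test_binning_seeds_centers_from_self_peaks():
    design = _design()
    peaks = {label: {"p": []} for label in design.samples}
    for tp in TIMEPOINTS:
        peaks[f"{A}x{A}_{tp}"]["p"] = [100.0, 150.2]
        peaks[f"{B}x{B}_{tp}"]["p"] = [100.4]          # same bin as 100.0
        peaks[f"{A}x{B}_{tp}"]["p"] = [150.0, 222.0]   # 222 matches no self bin
        peaks[f"{B}x{A}_{tp}"]["p"] = [99.8]
    table = build_allele_table(peaks, design)
    centers = sorted({center for _, center in table.keys})
    assert centers == [100.0, 150.2]
    assert table.provenance["dropped_nonparental_peaks"] == len(TIMEPOINTS)
    # 150.x allele: in the A self and the A-mother F1, absent elsewhere
    assert table.present(("p", 150.2), f"{A}x{A}_3")
    assert table.present(("p", 150.2), f"{A}x{B}_3")
    assert not table.present(("p", 150.2), f"{B}x{B}_3")
    carriers = detect_polymorphic(table, design)
    assert carriers == {("p", 150.2): A}
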