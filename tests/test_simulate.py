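import numpy as np
import pytest

from cernaflow.errors import ConfigurationError
from cernaflow.model import SequenceRecord
from cernaflow.seeds import scan
from cernaflow.simulate import (
    SimulationConfig,
    TruthSet,
    simulate_all,
    simulate_expression,
    simulate_sequences,
)


class TestDeterminism:
    def test_identical_seed_identical_matrices(self):
        m1, t1 = simulate_expression(SimulationConfig(seed=5))
        m2, t2 = simulate_expression(SimulationConfig(seed=5))
        for cls in m1:
            assert m1[cls].values.equals(m2[cls].values)
        assert t1.to_json() == t2.to_json()

    def test_identical_seed_identical_sequences(self):
        s1 = simulate_all(SimulationConfig(seed=6))
        s2 = simulate_all(SimulationConfig(seed=6))
        assert {k: v.sequence for k, v in s1.sequences.items()} == \
            {k: v.sequence for k, v in s2.sequences.items()}

    def test_different_seeds_differ(self):
        m1, _ = simulate_expression(SimulationConfig(seed=1))
        m2, _ = simulate_expression(SimulationConfig(seed=2))
        assert not m1["mRNA"].values.equals(m2["mRNA"].values)


class TestPlantedExpression:
    def test_zero_de_fraction_gives_empty_truth(self):
        cfg = SimulationConfig(seed=3, de_fraction=0.0, n_cerna_triplets=0,
                               n_coexpressed_pairs=0)
        _, truth = simulate_expression(cfg)
        assert truth.de_transcripts == {}

    def test_planted_pair_pcc_approaches_one_as_residual_vanishes(self):
        cfg = SimulationConfig(seed=4, coexpr_residual_sd=1e-9)
        matrices, truth = simulate_expression(cfg)
        log = np.log2(np.vstack([matrices["lncRNA"].values.to_numpy(),
                                 matrices["mRNA"].values.to_numpy()]))
        ids = (matrices["lncRNA"].transcript_ids
               + matrices["mRNA"].transcript_ids)
        idx = {t: i for i, t in enumerate(ids)}
        for lnc, mrna, sign in truth.coexpressed_pairs:
            r = np.corrcoef(log[idx[lnc]], log[idx[mrna]])[0, 1]
            assert abs(r) > 1 - 1e-6
            assert (r > 0) == (sign == "positive")

    def test_planted_effect_calibration(self):
        """Mean observed log2FC of >= 200 planted effects of exactly 2 is
        within +/- 0.1 of 2 at the default noise level."""
        cfg = SimulationConfig(seed=8, n_mrna=300, de_fraction=0.8,
                               log2fc_mean=2.0, log2fc_sd=0.0,
                               n_cerna_triplets=0, n_coexpressed_pairs=0)
        matrices, truth = simulate_expression(cfg)
        m = matrices["mRNA"]
        case = m.values[m.samples_in_group("case")].mean(axis=1)
        ctrl = m.values[m.samples_in_group("control")].mean(axis=1)
        observed = np.log2(case / ctrl)
        planted = [t for t in truth.de_transcripts if t.startswith("MRNA")]
        assert len(planted) >= 200
        signed = [observed[t] * (1 if truth.de_transcripts[t]["direction"] == "up"
                                 else -1) for t in planted]
        assert np.mean(signed) == pytest.approx(2.0, abs=0.1)

    def test_triplet_sign_structure(self, study):
        truth = study.truth
        for circ, mir, mrna in truth.cerna_triplets:
            d = {t: truth.de_transcripts[t]["direction"]
                 for t in (circ, mir, mrna)}
            assert d[circ] == d[mrna] != d[mir]

    def test_structure_budget_validated(self):
        cfg = SimulationConfig(n_circrna=4, n_cerna_triplets=5)
        with pytest.raises(ConfigurationError):
            simulate_expression(cfg)


class TestPlantedSequences:
    def test_every_planted_site_is_realized_exactly(self, study):
        for mir_id, target_id, site_type, pos, junction in \
                study.truth.planted_sites:
            hits = scan(study.sequences[mir_id], study.sequences[target_id])
            assert [(h.site_type, h.start, h.spans_junction) for h in hits] \
                == [(site_type, pos, junction)]

    def test_background_targets_are_scrubbed(self, study):
        """Scanning any non-planted target with any simulated miRNA finds
        zero sites."""
        planted_targets = {t for _, t, *_ in study.truth.planted_sites}
        mirnas = [study.sequences[k] for k in study.sequences
                  if k.startswith("MIR")]
        backgrounds = [v for k, v in study.sequences.items()
                       if k.startswith(("MRNA", "CIRC"))
                       and k not in planted_targets]
        assert backgrounds
        for target in backgrounds:
            for mir in mirnas:
                assert scan(mir, target) == []

    def test_junction_sites_need_circular_topology(self, study):
        junction_sites = [(m, t, st, p) for m, t, st, p, j in
                          study.truth.planted_sites if j]
        if not junction_sites:
            pytest.skip("no junction-spanning site drawn for this seed")
        for mir_id, target_id, site_type, pos in junction_sites:
            circ = study.sequences[target_id]
            linear = SequenceRecord(id=circ.id, sequence=circ.sequence,
                                    topology="linear")
            assert any(h.spans_junction for h in
                       scan(study.sequences[mir_id], circ))
            assert not any(h.start == pos and h.site_type == site_type
                           for h in scan(study.sequences[mir_id], linear))

    def test_sequences_respect_requested_lengths(self, study):
        cfg = study.config
        assert all(len(study.sequences[f"MRNA{i:04d}"]) == cfg.utr_length
                   for i in range(cfg.n_mrna))
        assert all(len(study.sequences[f"CIRC{i:04d}"]) == cfg.circ_length
                   for i in range(cfg.n_circrna))

    def test_sequences_deterministic_given_truth(self):
        cfg = SimulationConfig(seed=12)
        _, truth_a = simulate_expression(cfg)
        _, truth_b = simulate_expression(cfg)
        seq_a = simulate_sequences(cfg, truth_a)
        seq_b = simulate_sequences(cfg, truth_b)
        assert {k: v.sequence for k, v in seq_a.items()} == \
            {k: v.sequence for k, v in seq_b.items()}


class TestTruthSerialization:
    def test_round_trip(self, study):
        text = study.truth.to_json()
        back = TruthSet.from_json(text)
        assert back.to_json() == text
        assert back.cerna_triplets == [tuple(t) for t in
                                       study.truth.cerna_triplets]
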