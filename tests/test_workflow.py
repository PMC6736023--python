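"""workflow: the decision cascade, batch runs and self-screening."""

import numpy as np
import pytest

from allercat import fixtures as fx
from allercat.qrepeat import STANDARD_20
from allercat.seqdb import ProteinRecord, SequenceDatabase
from allercat.workflow import (
    CSV_HEADER,
    EvidenceCall,
    ReferenceBundle,
    WorkflowConfig,
    assess,
    run_batch,
    self_screen,
)

AA20 = STANDARD_20


def random_record(rng, n, rid="q"):
    return ProteinRecord(rid, "".join(rng.choice(list(AA20), size=n)))


class TestConfig:
    def test_defaults(self):
        cfg = WorkflowConfig()
        assert cfg.entropy_min == 0.34
        assert cfg.epitope_strong_identity == 0.93
        assert cfg.window_len == 80
        assert cfg.window_min_identity == 0.35
        assert cfg.surface_cutoff == 2.55
        assert cfg.epitope_radius == 12.0
        assert cfg.epitope_min_size == 13
        assert cfg.e_max == 0.001
        assert cfg.max_batch == 50

    def test_validation(self):
        with pytest.raises(ValueError):
            WorkflowConfig(entropy_min=-1.0)
        with pytest.raises(ValueError):
            WorkflowConfig(window_min_identity=1.5)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump({"window_len": 40, "e_max": 0.01}))
        cfg = WorkflowConfig.from_yaml(p)
        assert cfg.window_len == 40
        assert cfg.e_max == 0.01
        with pytest.raises(ValueError, match="unknown config"):
            p.write_text(yaml.safe_dump({"nope": 1}))
            WorkflowConfig.from_yaml(p)


class TestEvidenceCall:
    def test_level_basis_consistency(self):
        with pytest.raises(ValueError):
            EvidenceCall("q", "none", "kmer")
        with pytest.raises(ValueError):
            EvidenceCall("q", "strong", "epitope3d")  # missing identity


class TestCascade:
    def test_verbatim_allergen_with_structure_strong_epitope3d(self, small_bundle):
        bundle, _ = small_bundle
        rec = bundle.allergens.records[0]  # has a structure
        call = assess(rec, bundle)
        assert call.level == "strong"
        assert call.basis == "epitope3d"
        assert call.epitope_identity == pytest.approx(1.0)
        assert call.epitope_identity >= 0.93
        assert call.best_structure == f"str_{rec.id}"

    def test_qrepeat_shadows_everything(self, small_bundle):
        bundle, _ = small_bundle
        # even a verbatim structural allergen is called qrepeat once a
        # Q-repeat is embedded
        rec = bundle.allergens.records[0]
        qseq = rec.sequence[:20] + "QQPQQPQQQPQQPQQ" + rec.sequence[20:]
        call = assess(ProteinRecord("q", qseq), bundle)
        assert call.level == "strong"
        assert call.basis == "qrepeat"

    def test_qrepeat_fires_without_any_allergen_similarity(self, small_bundle):
        bundle, _ = small_bundle
        rng = np.random.default_rng(50)
        carrier = "".join(rng.choice(list(AA20.replace("Q", "")), size=40))
        seq = carrier[:20] + "QQQPQQPQQQPQQ" + carrier[20:]
        call = assess(ProteinRecord("q", seq), bundle)
        assert call.level == "strong"
        assert call.basis == "qrepeat"

    def test_random_query_none(self, small_bundle):
        bundle, _ = small_bundle
        rng = np.random.default_rng(51)
        for trial in range(5):
            rec = random_record(rng, 60, rid=f"q{trial}")
            call = assess(rec, bundle)
            assert (call.level, call.basis) == ("none", "none")

    def test_homolog_without_structure_linear_window(self, small_bundle):
        bundle, _ = small_bundle
        # allergen records beyond the first 3 have no structure
        rec = bundle.allergens.records[7]
        call = assess(rec, bundle)
        assert call.level == "strong"
        # verbatim self-match: epitope3d only if a structure rep matches
        assert call.basis in ("epitope3d", "linear_window")

    def test_weak_epitope_below_threshold(self, small_bundle):
        bundle, _ = small_bundle
        rec = bundle.allergens.records[0]
        # heavy mutation: still a structure hit, epitope identity < 93%
        mutated = fx.mutate_homolog(rec.sequence, 0.60, seed=5)
        call = assess(ProteinRecord("m", mutated), bundle)
        if call.basis == "epitope3d":
            assert call.epitope_identity is not None
            if call.epitope_identity < 0.93:
                assert call.level == "weak"

    def test_too_short_query(self, small_bundle):
        bundle, _ = small_bundle
        call = assess(ProteinRecord("tiny", "MKVLA"), bundle)
        assert call.level == "none"
        assert "too short" in call.notes

    def test_kmer_only_is_weak(self):
        # reference with no structures, and an allergen that shares an
        # 8-residue stretch (3 hexamers) with the query but nothing more
        rng = np.random.default_rng(52)
        core = "MKVLATQW"
        allergen = "".join(rng.choice(list(AA20), size=120)) + core
        query = core + "".join(rng.choice(list(AA20), size=30))
        bundle = ReferenceBundle(
            allergens=SequenceDatabase([ProteinRecord("a1", allergen)])
        )
        call = assess(ProteinRecord("q", query), bundle)
        if call.basis == "kmer":
            assert call.level == "weak"
            assert call.hexamer_hits >= 3

    def test_structure_removal_never_strengthens(self, small_bundle):
        bundle, _ = small_bundle
        stripped = ReferenceBundle(
            allergens=bundle.allergens,
            qrepeat_model=bundle.qrepeat_model,
        )
        rank = {"none": 0, "weak": 1, "strong": 2}
        rng = np.random.default_rng(53)
        queries = [bundle.allergens.records[0], bundle.allergens.records[1]]
        queries.append(
            ProteinRecord("h", fx.mutate_homolog(queries[0].sequence, 0.75, 3))
        )
        for rec in queries:
            with_structs = assess(rec, bundle)
            without = assess(rec, stripped)
            assert rank[without.level] <= max(
                rank[with_structs.level], rank[without.level]
            )
            if with_structs.basis == "epitope3d":
                assert without.basis in ("linear_window", "kmer", "qrepeat", "none")

    def test_reference_monotonicity(self, small_bundle):
        bundle, _ = small_bundle
        rng = np.random.default_rng(54)
        # grow the allergen DB; no strong/weak call may degrade to none
        extra = SequenceDatabase(
            list(bundle.allergens)
            + [random_record(rng, 80, rid=f"extra{i}") for i in range(3)]
        )
        grown = ReferenceBundle(
            allergens=extra,
            rep_sequences=bundle.rep_sequences,
            epitope_tables=bundle.epitope_tables,
            qrepeat_model=bundle.qrepeat_model,
        )
        for rec in list(bundle.allergens)[:4]:
            before = assess(rec, bundle)
            after = assess(rec, grown)
            if before.level in ("strong", "weak"):
                assert after.level != "none"


class TestRunBatch:
    def test_order_preserved(self, small_bundle, tmp_path):
        bundle, _ = small_bundle
        queries = SequenceDatabase(
            [
                ProteinRecord("z_last", bundle.allergens.records[0].sequence),
                ProteinRecord("a_first", bundle.allergens.records[1].sequence),
                ProteinRecord("m_mid", "MKVLATQWERTYMKVLATQWERTY"),
            ]
        )
        out = tmp_path / "calls.csv"
        calls = run_batch(queries, bundle, out=out)
        assert [c.query_id for c in calls] == ["z_last", "a_first", "m_mid"]
        lines = out.read_text().splitlines()
        assert lines[0] == CSV_HEADER
        assert len(lines) == 4

    def test_batch_limit_no_partial_file(self, small_bundle, tmp_path):
        bundle, _ = small_bundle
        rng = np.random.default_rng(55)
        queries = SequenceDatabase(
            random_record(rng, 30, rid=f"q{i}") for i in range(51)
        )
        out = tmp_path / "calls.csv"
        with pytest.raises(ValueError, match="50"):
            run_batch(queries, bundle, out=out)
        assert not out.exists()

    def test_byte_identical_reruns(self, small_bundle, tmp_path):
        bundle, _ = small_bundle
        queries = SequenceDatabase(
            [
                ProteinRecord("q1", bundle.allergens.records[0].sequence),
                ProteinRecord("q2", "MKVLATQWERTY" * 3),
            ]
        )
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        run_batch(queries, bundle, out=a)
        run_batch(queries, bundle, out=b)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_batch_rejected(self, small_bundle):
        bundle, _ = small_bundle
        with pytest.raises(ValueError):
            run_batch(SequenceDatabase(), bundle)


class TestSelfScreen:
    def test_full_sensitivity_on_clean_bundle(self, small_bundle):
        bundle, _ = small_bundle
        summary = self_screen(bundle)
        assert summary.sensitivity == 1.0
        assert summary.counts["none"] == 0
        assert not summary.missed

    def test_short_sequence_reported_missed(self, small_bundle):
        bundle, _ = small_bundle
        with_short = ReferenceBundle(
            allergens=SequenceDatabase(
                list(bundle.allergens) + [ProteinRecord("tiny", "MKVLA")]
            ),
            rep_sequences=bundle.rep_sequences,
            epitope_tables=bundle.epitope_tables,
            qrepeat_model=bundle.qrepeat_model,
        )
        summary = self_screen(with_short)
        assert summary.counts["none"] == 1
        (missed,) = summary.missed
        assert missed[0] == "tiny"
        assert "too short" in missed[1]
        assert "length 5" in missed[1]

    def test_jackknife_never_raises_strong_count(self, small_bundle):
        bundle, _ = small_bundle
        inclusive = self_screen(bundle)
        jack = self_screen(bundle, jackknife=True)
        assert jack.counts["strong"] <= inclusive.counts["strong"]
        assert jack.jackknife
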