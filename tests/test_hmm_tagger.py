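"""HMM training, Viterbi / n-best decoding vs enumeration, rescoring, tagging."""

import io
import itertools

import numpy as np
import pytest

from charhmm.corpus_io import AnnotatedDocument, ConceptSpan, Corpus
from charhmm.hmm_tagger import (
    STOP,
    Candidate,
    HmmModel,
    TaggerConfig,
    legal_start,
    legal_successors,
    load_model,
    nbest_decode,
    rescore,
    save_model,
    split_sentences_80_20,
    tag,
    train_full,
    train_hmm,
    train_rescorer,
    viterbi_decode,
)
from charhmm.synthetic_data import generate_corpus, i2b2_like
from charhmm.tag_schemes import (
    bio_to_bmewo_plus,
    label_inventory,
    spans_to_bio,
)


def toy_model(rng, n_labels, n_tokens):
    """Random dense HMM with fake emissions; returns (model, emission matrix)."""
    labels = [f"L{i}" for i in range(n_labels)]
    start = np.log(rng.dirichlet(np.ones(n_labels)))
    rows = np.log(rng.dirichlet(np.ones(n_labels + 1), size=n_labels))
    E = np.log(rng.dirichlet(np.ones(n_tokens + 1), size=n_labels))[:, :n_tokens].T

    class Fixed(HmmModel):
        def emission_matrix(self, tokens):
            return E[: len(tokens)]

    model = Fixed(
        labels=labels,
        type_inventory=[],
        max_n=1,
        start_logp=start,
        trans_logp=rows[:, :n_labels],
        stop_logp=rows[:, n_labels],
        emission_lms={},
    )
    return model, E


def enumerate_scores(model, E, T):
    """Exhaustive path scores, best first (independent oracle)."""
    L = len(model.labels)
    out = []
    for seq in itertools.product(range(L), repeat=T):
        s = model.start_logp[seq[0]] + E[0, seq[0]]
        for t in range(1, T):
            s += model.trans_logp[seq[t - 1], seq[t]] + E[t, seq[t]]
        s += model.stop_logp[seq[-1]]
        out.append((s, [model.labels[i] for i in seq]))
    out.sort(key=lambda x: -x[0])
    return out


class TestDecoderOracle:
    @pytest.mark.parametrize("trial", range(30))
    def test_viterbi_equals_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        L, T = int(rng.integers(2, 8)), int(rng.integers(1, 7))
        model, E = toy_model(rng, L, T)
        best_score, best_seq = enumerate_scores(model, E, T)[0]
        labels, score = viterbi_decode(model, ["x"] * T)
        assert score == pytest.approx(best_score, abs=1e-9)
        assert labels == best_seq

    @pytest.mark.parametrize("trial", range(30))
    def test_nbest_matches_sorted_enumeration(self, trial):
        rng = np.random.default_rng(2000 + trial)
        L, T = int(rng.integers(2, 6)), int(rng.integers(1, 5))
        model, E = toy_model(rng, L, T)
        n = 9
        cands = nbest_decode(model, ["x"] * T, n)
        oracle = enumerate_scores(model, E, T)[:n]
        assert len(cands) == min(n, L**T)
        for cand, (score, seq) in zip(cands, oracle):
            assert cand.base_score == pytest.approx(score, abs=1e-9)
            assert cand.labels == seq

    def test_nbest_first_is_viterbi_and_sorted_distinct(self):
        rng = np.random.default_rng(3)
        model, E = toy_model(rng, 5, 4)
        tokens = ["x"] * 4
        cands = nbest_decode(model, tokens, 12)
        vl, vs = viterbi_decode(model, tokens)
        assert cands[0].labels == vl
        assert cands[0].base_score == pytest.approx(vs)
        scores = [c.base_score for c in cands]
        assert scores == sorted(scores, reverse=True)
        assert len({tuple(c.labels) for c in cands}) == len(cands)

    def test_n_below_one_rejected(self):
        rng = np.random.default_rng(4)
        model, _ = toy_model(rng, 3, 2)
        with pytest.raises(ValueError):
            nbest_decode(model, ["x"], 0)


class TestTrainHmm:
    def make_corpus(self):
        docs = [
            AnnotatedDocument(
                "d0",
                [["arin", "x", "parin"], ["qol", "y"]],
                [
                    ConceptSpan(0, 0, 1, "X"),
                    ConceptSpan(0, 2, 3, "X"),
                    ConceptSpan(1, 0, 1, "Y"),
                ],
            )
        ]
        return Corpus(docs, ["X", "Y"])

    def test_single_observation_start_is_modal(self):
        corpus = Corpus(
            [AnnotatedDocument("d", [["a"]], [ConceptSpan(0, 0, 1, "X")])], ["X"]
        )
        model = train_hmm(corpus, max_n=2)
        w_x = model.labels.index("W_X")
        assert np.argmax(model.start_logp) == w_x

    def test_transition_rows_normalize(self):
        model = train_hmm(self.make_corpus(), max_n=3)
        assert np.exp(model.start_logp).sum() == pytest.approx(1.0, abs=1e-9)
        total = np.exp(model.trans_logp).sum(axis=1) + np.exp(model.stop_logp)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_typed_morphology_separates_emissions(self):
        rng = np.random.default_rng(0)
        docs = []
        for d in range(30):
            sents, spans = [], []
            for si in range(2):
                wx = "".join(rng.choice(list("bdgm"), 3)) + "in"
                wy = "".join(rng.choice(list("cfkl"), 3)) + "ol"
                sents.append([wx, "the", wy])
                spans += [ConceptSpan(si, 0, 1, "X"), ConceptSpan(si, 2, 3, "Y")]
            docs.append(AnnotatedDocument(f"d{d}", sents, spans))
        model = train_hmm(Corpus(docs, ["X", "Y"]), max_n=5)
        assert model.emission_logp("W_X", "arin") > model.emission_logp("W_Y", "arin")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_hmm(Corpus([], ["X"]), ["X"])

    def test_gold_sequences_are_legal_paths(self, corpus_factory):
        """The successor rules must admit every encoder output."""
        for seed in range(10):
            corpus = corpus_factory(seed)
            types = corpus.type_inventory
            for doc in corpus.documents:
                for si, sent in enumerate(doc.sentences):
                    bio = spans_to_bio(len(sent), doc.spans_in_sentence(si))
                    labs = bio_to_bmewo_plus(bio)
                    assert labs[0] in legal_start(types)
                    for a, b in zip(labs, labs[1:]):
                        assert b in legal_successors(a, types), (a, b)
                    assert STOP in legal_successors(labs[-1], types)


class TestRescorer:
    def make_corpus(self, rng):
        docs = []
        for d in range(20):
            sents, spans = [], []
            for si in range(2):
                pain = ["chest", "pain"]
                drug = ["aspirin"]
                sents.append(pain + ["and"] + drug)
                spans += [ConceptSpan(si, 0, 2, "Problem"), ConceptSpan(si, 3, 4, "Treatment")]
            docs.append(AnnotatedDocument(f"d{d}", sents, spans))
        return Corpus(docs, ["Problem", "Treatment"])

    def test_chunk_lm_learns_chunk_language(self):
        corpus = self.make_corpus(np.random.default_rng(0))
        resc = train_rescorer(corpus, max_n=8)
        lm = resc.chunk_lms["Problem"]
        assert lm.log_prob("chest pain") > lm.log_prob("aspirin")

    def test_type_with_no_chunks_gets_ground_model(self):
        corpus = Corpus(
            [AnnotatedDocument("d", [["a", "b"]], [ConceptSpan(0, 0, 1, "X")])],
            ["X"],
        )
        resc = train_rescorer(corpus, ["X", "Y"], max_n=3)
        assert resc.chunk_lms["Y"].counts == {}
        assert resc.chunk_lms["Y"].log_prob("a") < 0  # total, finite

    def test_single_candidate_returned(self):
        corpus = self.make_corpus(np.random.default_rng(0))
        resc = train_rescorer(corpus, max_n=8)
        cand = Candidate(labels=bio_to_bmewo_plus(["B_Problem", "I_Problem", "O", "O"]),
                         base_score=-1.0)
        best = rescore([cand], resc, ["chest", "pain", "and", "rest"])
        assert best is cand
        assert best.rescored_score is not None

    def test_rescoring_invariant_to_candidate_order(self):
        corpus = self.make_corpus(np.random.default_rng(0))
        resc = train_rescorer(corpus, max_n=8)
        tokens = ["chest", "pain", "and", "aspirin"]
        seqs = [
            ["B_Problem", "I_Problem", "O", "O"],
            ["O", "O", "O", "B_Treatment"],
            ["B_Problem", "I_Problem", "O", "B_Treatment"],
        ]
        cands = [
            Candidate(labels=bio_to_bmewo_plus(s), base_score=-float(i))
            for i, s in enumerate(seqs)
        ]
        best1 = rescore(list(cands), resc, tokens)
        best2 = rescore(list(reversed(cands)), resc, tokens)
        assert best1.labels == best2.labels

    def test_aligned_candidate_wins(self):
        corpus = self.make_corpus(np.random.default_rng(0))
        resc = train_rescorer(corpus, max_n=8)
        tokens = ["chest", "pain", "and", "aspirin"]
        aligned = bio_to_bmewo_plus(["B_Problem", "I_Problem", "O", "B_Treatment"])
        split = bio_to_bmewo_plus(["B_Problem", "O", "O", "B_Treatment"])
        cands = [Candidate(split, -1.0), Candidate(aligned, -2.0)]
        assert rescore(cands, resc, tokens).labels == aligned


class TestTrainFull:
    def test_80_20_sentence_split(self):
        corpus, _ = generate_corpus(i2b2_like(0))
        base, resc = split_sentences_80_20(corpus, TaggerConfig(seed=5))
        n = corpus.n_sentences
        assert base.n_sentences + resc.n_sentences == n
        # ceil(0.8 n) per document; overall close to 80%
        assert 0.75 <= base.n_sentences / n <= 0.9

    def test_ten_sentences_split_8_2(self):
        doc = AnnotatedDocument("d", [[f"w{i}"] for i in range(10)], [])
        corpus = Corpus([doc], [])
        base, resc = split_sentences_80_20(corpus, TaggerConfig(seed=0))
        assert base.n_sentences == 8
        assert resc.n_sentences == 2

    def test_split_is_deterministic_per_seed(self):
        corpus, _ = generate_corpus(i2b2_like(1))
        a1, b1 = split_sentences_80_20(corpus, TaggerConfig(seed=7))
        a2, b2 = split_sentences_80_20(corpus, TaggerConfig(seed=7))
        assert [d.sentences for d in a1.documents] == [d.sentences for d in a2.documents]
        assert [d.sentences for d in b1.documents] == [d.sentences for d in b2.documents]

    def test_too_small_corpus_rejected(self):
        doc = AnnotatedDocument("d", [["a"], ["b"]], [])
        with pytest.raises(ValueError, match="80/20"):
            train_full(Corpus([doc], ["X"]), ["X"])

    def test_same_seed_same_model_file(self):
        corpus, _ = generate_corpus(i2b2_like(2))
        cfg = TaggerConfig(max_n=4, nbest_size=4, seed=3)
        payloads = []
        for _ in range(2):
            model = train_full(corpus, config=cfg)
            buf = io.StringIO()
            save_model(model, buf)
            payloads.append(buf.getvalue())
        assert payloads[0] == payloads[1]

    def test_strategy_label_sets(self):
        corpus, _ = generate_corpus(i2b2_like(0))
        full = train_full(corpus, config=TaggerConfig(max_n=3, nbest_size=2))
        single = train_full(corpus, ["Problem"], TaggerConfig(max_n=3, nbest_size=2))
        # BIO views: 7 labels for 3 types, 3 for a singleton
        assert len(label_inventory(full.type_inventory, "bio")) == 7
        assert len(label_inventory(single.type_inventory, "bio")) == 3
        assert len(full.base.labels) == 7 * 3 + 4
        assert len(single.base.labels) == 7 * 1 + 4


@pytest.fixture(scope="module")
def trained():
    """Tagger trained on 40 of 50 synthetic documents; the rest held out."""
    corpus, _ = generate_corpus(i2b2_like(0))
    model = train_full(
        corpus.subset(range(40)), config=TaggerConfig(max_n=8, nbest_size=8, seed=0)
    )
    return model, corpus


class TestTag:

    def test_empty_document_no_spans(self, trained):
        model, _ = trained
        assert tag(model, []) == []

    def test_output_spans_are_valid_and_nonoverlapping(self, trained):
        model, corpus = trained
        for doc in corpus.documents[:5]:
            spans = tag(model, doc)
            AnnotatedDocument("check", doc.sentences, spans)  # validates

    def test_recovers_spans_on_separable_corpus(self, trained):
        """Parameter recovery: held-out micro-F >= 0.8 on a separable document set."""
        from charhmm.experiments import evaluate

        model, corpus = trained
        heldout = corpus.documents[40:]
        gold = {d.doc_id: d.spans for d in heldout}
        pred = {d.doc_id: tag(model, d) for d in heldout}
        res = evaluate(gold, pred, types=corpus.type_inventory)
        tp = sum(res.tp(t) for t in corpus.type_inventory)
        fp = sum(res.fp(t) for t in corpus.type_inventory)
        fn = sum(res.fn(t) for t in corpus.type_inventory)
        f = 2 * tp / (2 * tp + fp + fn)
        assert f >= 0.8

    def test_model_serialization_round_trip(self, trained):
        model, corpus = trained
        buf = io.StringIO()
        save_model(model, buf)
        buf.seek(0)
        back = load_model(buf)
        doc = corpus.documents[0]
        assert tag(back, doc) == tag(model, doc)
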