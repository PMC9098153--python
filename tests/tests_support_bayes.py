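"""Independent brute-force Bayes-rule oracle used by the acceptance checks."""

import smht


def brute_force_posterior(corpus, tokens, smoothing=1.0):
    """Exhaustive enumeration of the multinomial NB posterior, plain floats."""
    classes = sorted(set(corpus.labels), key=smht.SENTIMENT_CLASSES.index)
    vocab = corpus.vocabulary
    post = {}
    for c in classes:
        docs = [d for d, l in zip(corpus.documents, corpus.labels) if l == c]
        prior = len(docs) / len(corpus.documents)
        counts = {t: sum(d.count(t) for d in docs) for t in vocab}
        total = sum(counts.values())
        p = prior
        for tok in tokens:
            if tok in vocab:
                p *= (counts[tok] + smoothing) / (total + smoothing * len(vocab))
        post[c] = p
    z = sum(post.values())
    return {c: p / z for c, p in post.items()}
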