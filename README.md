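# scriptsurp

Quantifying how predictable an everyday event is from *script
knowledge* — stereotyped knowledge of how activities like cooking pasta
unfold — and using that to build and analyse psycholinguistic
experiments.

Predictability effects in language are usually estimated with n-gram
models over words, which only capture *linguistic* context.  For
discourse-initial utterances ("The pasta, please!") the relevant
context is extralinguistic.  `scriptsurp` implements the corpus-based
alternative: a script is a probabilistic event network whose states are
canonical verb–noun event labels ("pour pasta") and whose edges carry
transition probabilities p(e_j | e_i) estimated by an event-level
bigram language model over crowd-sourced event-sequence descriptions
(ESDs).  The predictability of an utterance is proxied by the surprisal
of the event it refers to,

    surprisal(e_j | e_i) = −log2 p(e_j | e_i)   [bits]

Greedy maximum-likelihood *event chains* through the network supply
experimental stimuli — three context events plus a predictable target
(the argmax successor) and an unpredictable target (probability 0 in
context) — and a cumulative link mixed model (CLMM) module analyses the
7-point Likert acceptability ratings such stimuli elicit, including the
subject-exclusion filter, sum coding, z-scored script familiarity,
Laplace-approximate estimation with crossed random effects, and
likelihood-ratio backward selection.

The package is aimed at researchers in computational psycholinguistics
who want empirically grounded event-probability estimates without
running norming studies, and at anyone needing a fully synthetic,
ground-truth-carrying test bed for such pipelines: the
`synthetic_data` module generates ESD corpora from known script graphs
(with synonym, pronoun, ellipsis and skipping noise) and rating tables
from known ordinal mixed models.

## Worked example

From a known pasta-cooking script graph, generate a corpus of 100 ESDs,
label it, fit the bigram event model, and extract the stimulus chain:

```python
import numpy as np
from scriptsurp.synthetic_data import ScriptGraph, NoiseSpec, sample_esd_corpus, make_lexicon
from scriptsurp.event_labeling import label_corpus
from scriptsurp.event_lm import fit_ngram, bits_to_percent
from scriptsurp.chain_extraction import auto_start, extract_chain, build_stimulus, propose_unpredictable

graph = ScriptGraph(
    states=("put water", "turn stove", "boil water", "pour pasta"),
    transition_matrix=np.array([
        [0.0, 0.8, 0.2, 0.0, 0.0],     # last column: script ends here
        [0.0, 0.0, 0.9, 0.1, 0.0],
        [0.0, 0.0, 0.0, 0.85, 0.15],
        [0.0, 0.0, 0.0, 0.0, 1.0]]),
    start_distribution=np.array([0.9, 0.1, 0.0, 0.0]),
)
noise = NoiseSpec(seed=0)
corpus, truth = sample_esd_corpus(graph, 100, noise, scenario="cooking pasta")
labeled = label_corpus(corpus, make_lexicon(graph, noise, "cooking pasta"))
model = fit_ngram(labeled.label_sequences, scenario="cooking pasta")

chain = extract_chain(model, auto_start(model, min_count=8), 4, min_count=8)
spec = build_stimulus(model, chain)
print(chain.events)
print([round(p, 3) for p in chain.transition_probs])
print(round(spec.target_bits, 3), bits_to_percent(spec.target_bits))
print(propose_unpredictable(model, spec.context_events[2],
                            ["set kitchen.table", "pour pasta"]))
```

prints

```
('put water', 'turn stove', 'boil water', 'pour pasta')
[0.795, 0.88, 0.767]
0.383 76.7
['set kitchen.table']
```

The chain is the graph's modal path: the fitted transition
probabilities (0.795, 0.88, 0.767) estimate the generating ones (0.8,
0.9, 0.85).  The predictable target "pour pasta" has a surprisal of
0.383 bits, i.e. a 76.7% likelihood after "boil water"; "set
kitchen.table" qualifies as an unpredictable target because it never
follows "boil water" in the corpus.  `bits_to_percent` is the same
conversion that maps 2.13 bits to a 22.8% likelihood and 2.18 bits to
22.1%.

A command-line interface wraps each stage
(`scriptsurp corpus summarize`, `label`, `fit`, `surprisal`, `chain`,
`stimuli`, `simulate`, `analyze`); run `scriptsurp --help`.

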