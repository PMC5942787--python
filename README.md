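# tpcorpus

Time-course analysis of melodic transitional probabilities in an ordered
symbolic-music corpus.

## The problem

A composer's output can be treated as sequential data: the melody line of
each piece is a tone sequence whose local regularities are captured by an
nth-order Markov chain.  The transitional probability of a melodic
transition is the conditional probability of the next tone given the
preceding *n* tones,

    P(e_{n+1} | e_n) = P(e_{n+1} ∩ e_n) / P(e_n),

estimated as a count ratio over all windows of n+1 consecutive tones.  To
make the statistics independent of key, every transition is re-expressed
relative to its first pitch — `(65, 63, 62, 60, 58)` becomes the interval
pattern `[0, -2, -3, -5, -7]` — so a pattern is shared by all of its
transpositions (relative pitch, not absolute pitch).

Given a corpus of pieces ordered in time (e.g. by opus/publication
number), the question is whether the probabilities of particular interval
patterns drift systematically over the composer's career.  The pipeline:

1. extract the **highest-pitch line** of each movement from MusicXML
   (topmost sounding pitch at each onset; ties and slurred repetitions
   merged; grace notes excluded);
2. count interval n-grams per movement and pool movements within a piece
   (weighted average of probabilities = pooled counts);
3. keep only **universal patterns** — those occurring in every piece;
4. regress the piece serial number on the pattern probabilities by
   **forward stepwise selection** (p-to-enter 0.05, p-to-remove 0.10)
   with multicollinearity screens VIF < 2 and condition index < 20,
   adopting the path model with the most predictors that passes the
   screens.

The package ships the transitional-probability matrices of the 32
Beethoven piano sonatas (highest-pitch lines, pooled over movements,
Markov orders 1–5) as packaged datasets, and a synthetic-corpus generator
that plants a linear drift in a designated pattern's probability so the
entire pipeline can be validated end to end by parameter recovery.

## Worked example

```python
import tpcorpus as tc

matrix = tc.load_beethoven_matrix(2)          # 32 sonatas x 37 patterns
results = tc.ProbabilityTrendModel(matrix).fit()
print(results.summary())
```

```
Markov order 2: 37 universal patterns, n = 32 pieces
Stepwise path: 4 accepted step(s)
Adopted model: 4 predictor(s), R2 = 0.599, adj R2 = 0.540, F(4,27) = 10.10, p = 3.949e-05
Intercept: 32.664
Variable       B   SE B   beta      p  VIF    CI
 0,-2,-4 -70.837 26.061 -0.362 0.0113 1.19 18.16
  0,0,-1 -50.354 14.968 -0.418 0.0023 1.04 18.16
 0,-4,-5  36.355 12.774  0.352 0.0083 1.03 18.16
  0,-2,0  42.294 17.087  0.323 0.0199 1.15 18.16
```

Four three-tone patterns carry a significant linear trend across the 32
sonatas: the probabilities of the descending patterns `[0,-2,-4]` and
`[0,0,-1]` fall over the composer's career (negative B), while
`[0,-4,-5]` and `[0,-2,0]` rise.  The model explains 54% of the variance
in serial number (adjusted R²), and all predictors pass the VIF < 2 and
CI < 20 collinearity screens.

Abstract patterns decode to concrete note names within a scale:

```python
tc.diatonic_instantiations(tc.IntervalPattern.from_string("0,-2,-3,-5,-7"))
# [('D', 'C', 'B', 'A', 'G'), ('G', 'F', 'E', 'D', 'C')]
```

— the five-tone descent is exactly a falling diatonic pentachord.

The same analysis runs from the shell:

```bash
tpcorpus reproduce --order 2 --out-dir out/        # packaged matrices
tpcorpus simulate corpus.csv --pieces 32 --length 2000 --seed 7
tpcorpus run corpus.csv --order 1 --order 2 --out-dir out/
```

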