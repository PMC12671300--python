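"""Quality control of a fluency transcript and ASR error measurement.

Builds a small phonematic ("S" words) transcript by hand, marks rule
violations (repetitions, cue mismatches), applies the exclusion rules,
and measures the word error rate of a simulated automatic transcription
against the corrected word list.
"""

from vftclust import Transcript, WordToken, mark_violations, qc_transcript, word_error_rate

tokens = tuple(
    WordToken(w, onset_s=t)
    for w, t in [("sonne", 1.8), ("salat", 4.2), ("sonne", 7.9),
                 ("tiger", 12.0), ("salami", 15.5)]
)
transcript = Transcript(task="phonematic", cue="S", tokens=tokens)

marked = mark_violations(transcript)
for tok in marked.tokens:
    print(f"{tok.surface:8s} flags={sorted(tok.flags) or '-'}")

qc = qc_transcript(marked)
print(f"violations: {qc.n_violations}/{qc.n_tokens} "
      f"(fraction {qc.violation_fraction:.2f}) excluded={qc.excluded}")
# 2 of 5 tokens violate the rules (a repeated word and a non-S word):
# 0.40 > 0.25, so this transcript is excluded from analysis.

auto = ["sonne", "salat", "tiger", "salami"]  # ASR missed one word
correct = [t.surface for t in transcript.tokens]
wer = word_error_rate(auto, correct)
print(f"word error rate: distance={wer.distance} normalized={wer.normalized:.2f}")
# One insertion is needed to repair the automatic transcript; dividing by
# the 5-word corrected list gives a normalized error rate of 0.20.
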