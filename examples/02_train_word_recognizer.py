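"""Train a small LSTM word recognizer and measure word error rate.

The model hears continuous streams of words and silence (20 dB per-band
noise) and is trained to activate the target word's output element for the
word's whole duration. Recognition reads out the most active word over each
token's final 100 ms. Takes a couple of minutes on one CPU.
"""

import cohortnet as cn
from cohortnet.lexicon import synthesize_all_tokens
from cohortnet.models import ModelConfig, TrainSchedule, make_stream_source

lex = cn.build_lexicon(30, 8, (3, 5), 0.6, seed=1, n_talkers=4)
tokens = synthesize_all_tokens(lex, seed=1)
train_keys, test_keys = cn.partition_tokens(lex, holdout_fraction=0.25, seed=1)
coding = cn.OutputCoding.localist(lex)

model = cn.build_model(ModelConfig(coding=coding, layer_sizes=[64], seed=0))
print(f"model: 64-unit LSTM, {model.core_parameter_count} core parameters")

source = make_stream_source({k: tokens[k] for k in train_keys}, coding, snr_db=20.0)
schedule = TrainSchedule(batch_size=32, chunk_frames=200, steps_per_epoch=6,
                         max_epochs=120, lr=7e-3, restart_every=40)
history = cn.train(model, source, schedule, seed=0)
print(f"trained {len(history['loss'])} epochs, best loss {history['best_loss']:.4f}")

ev = cn.build_evaluation_stream(tokens, train_keys, seed=1)
outputs, _ = cn.run_model(model, ev)
act = cn.to_activation(outputs, coding, lex)
train_anns = [a for a in ev.annotations if (a.word_id, a.talker_id) in train_keys]
test_anns = [a for a in ev.annotations if (a.word_id, a.talker_id) in test_keys]
print(f"WER on trained tokens: {cn.word_error_rate(act, train_anns):.3f} "
      "(fraction of tokens whose most active word is not the target)")
print(f"WER on held-out tokens: {cn.word_error_rate(act, test_anns):.3f} "
      "(novel talker renditions of trained words)")
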