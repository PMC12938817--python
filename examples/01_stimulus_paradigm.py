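"""The paired-pulse tone-train stimulus and its event schedule.

Builds the reference paradigm (2 s train of 25 ms, 800 Hz tones at 65 dB
with +15 dB increments at 1100 and 1700 ms), derives the shared event
clock, and renders the audio waveform.
"""

import numpy as np

from pulsegate import build_event_schedule, default_spec, synthesize_waveform

spec = default_spec()
sched = build_event_schedule(spec)

print(f"driving rate        : {spec.driving_rate_hz:g} Hz")
print(f"tones in the train  : {len(sched.tone_onsets_ms)}")
print(f"pulse onsets        : {sched.pulse_onsets_ms} ms")
print(f"elevated tone index : {sorted(sched.elevated_tone_indices)}")
print(f"amplitude ratio     : {spec.increment_amplitude_ratio:.4f} "
      f"(= 10^({spec.increment_db:g}/20))")

audio = synthesize_waveform(spec, sample_rate=44100)
rms_base = np.sqrt(np.mean(audio[:1102] ** 2))
print(f"waveform            : {audio.size} samples at 44.1 kHz, "
      f"baseline tone RMS {rms_base:.3f}")

# The pulse onsets sit on the 25 ms tone grid, so a +15 dB increment simply
# rescales two consecutive tones; every analysis window downstream is
# expressed on this same clock.
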