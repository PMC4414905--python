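cue	polarity
recommend	positive
satisfied	positive
wonderful experience	positive
really pleased	positive
thankful	positive
disappointed	negative
never again	negative
terrible experience	negative
not recommend	negative
regret	negative
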