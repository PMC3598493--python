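from hypothesis import settings

settings.register_profile("suite", derandomize=True)
settings.load_profile("suite")
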