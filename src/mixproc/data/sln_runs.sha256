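bbb47cccca7d7b817ca800f07dd05d9e4c83449beb106358fb6a6f8fe7c45365
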