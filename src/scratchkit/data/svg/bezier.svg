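<svg xmlns="http://www.w3.org/2000/svg" width="100" height="100" viewBox="0 0 100 100">
  <path d="M 10 50 C 30 5 70 95 90 50"/>
</svg>
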