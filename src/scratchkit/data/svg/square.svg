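<svg xmlns="http://www.w3.org/2000/svg" width="100" height="100" viewBox="0 0 100 100">
  <rect x="20" y="20" width="60" height="60"/>
</svg>
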