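<svg xmlns="http://www.w3.org/2000/svg" width="100" height="100" viewBox="0 0 100 100">
  <path d="M 5 5 H 95 V 95 H 5 V 15 H 85 V 85 H 15 V 25 H 75 V 75 H 25 V 35 H 65 V 65 H 35 V 45 H 55 V 55 H 45"/>
</svg>
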