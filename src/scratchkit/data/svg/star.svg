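<svg xmlns="http://www.w3.org/2000/svg" width="100" height="100" viewBox="0 0 100 100">
  <polygon points="50.0000,10.0000 40.5954,37.0557 11.9577,37.6393 34.7831,54.9443 26.4886,82.3607 50.0000,66.0000 73.5114,82.3607 65.2169,54.9443 88.0423,37.6393 59.4046,37.0557"/>
</svg>
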