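productivity,fertility,main_class,mire_class
productive,rich,spruce_mire,1
productive,rich,pine_mire,1
productive,rich,open_bog,2
productive,medium,spruce_mire,1
productive,medium,pine_mire,1
productive,medium,open_bog,2
productive,poor,spruce_mire,1
productive,poor,pine_mire,1
productive,poor,open_bog,4
poorly_productive,rich,spruce_mire,3
poorly_productive,rich,pine_mire,3
poorly_productive,rich,open_bog,2
poorly_productive,medium,spruce_mire,3
poorly_productive,medium,pine_mire,3
poorly_productive,medium,open_bog,3
poorly_productive,poor,spruce_mire,4
poorly_productive,poor,pine_mire,4
poorly_productive,poor,open_bog,4
unproductive,rich,spruce_mire,3
unproductive,rich,pine_mire,3
unproductive,rich,open_bog,2
unproductive,medium,spruce_mire,3
unproductive,medium,pine_mire,3
unproductive,medium,open_bog,3
unproductive,poor,spruce_mire,4
unproductive,poor,pine_mire,4
unproductive,poor,open_bog,4
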