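cluster,municipality,adjusted_rate,predicted_rate,population_thousands
1,Rio Grande,160.0,124.5,205.2
1,Bagé,157.3,126.3,121.0
1,Canguçu,138.9,111.4,55.3
1,Jaguarão,154.0,125.1,28.6
1,Capão Do Leão,127.0,121.7,25.2
1,Piratini,149.6,124.9,20.6
1,Arroio Grande,139.8,126.5,19.0
1,Pinheiro Machado,144.6,117.0,13.1
1,Candiota,138.6,128.6,9.2
1,Pedro Osório,143.4,124.7,8.0
1,Herval,133.6,124.8,7.0
1,Cerrito,113.3,97.9,6.5
1,Morro Redondo,113.8,110.4,6.5
1,Hulha Negra,141.3,115.1,6.3
1,Aceguá,145.5,128.8,4.6
1,Pedras Altas,126.8,80.1,2.2
2,Porto Velho,131.0,103.2,475.7
2,Candeias Do Jamari,85.4,70.5,22.4
3,Barueri,160.7,122.4,253.9
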