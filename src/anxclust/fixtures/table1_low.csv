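country,group,anxiety_pct,cluster
Australia,low,70,H-1
Uruguay,low,70,H-1
Chinese Taipei,low,69,H-1
Montenegro,low,69,H-1
Spain,low,69,H-1
Ireland,low,67,H-1
Macao (China),low,67,H-1
Peru,low,67,H-1
Portugal,low,67,H-1
Slovenia,low,67,H-1
Greece,low,66,H-1
Qatar,low,66,H-1
Hong Kong (China),low,65,H-1
Canada,low,65,H-1
Mexico,low,66,H-1
Thailand,low,64,H-1
Brazil,low,82,H-2
Dominican Republic,low,81,H-2
Colombia,low,79,H-2
Costa Rica,low,79,H-2
Malaysia,low,77,H-2
Singapore,low,77,H-2
United Kingdom,low,76,H-2
United States,low,76,H-2
New Zealand,low,74,H-2
Finland,low,46,L-1
Netherlands,low,44,L-1
Germany,low,43,L-1
Slovak Republic,low,43,L-1
Russia,low,41,L-1
Latvia,low,40,L-1
Switzerland,low,39,L-1
Czech Republic,low,35,L-1
Estonia,low,53,L-2
Israel,low,52,L-2
Lithuania,low,52,L-2
Luxembourg,low,52,L-2
France,low,51,L-2
Poland,low,51,L-2
Belgium,low,50,L-2
Chile,low,63,L-3
Denmark,low,63,L-3
Japan,low,63,L-3
Turkey,low,63,L-3
Hungary,low,62,L-3
Cyprus,low,61,L-3
Tunisia,low,61,L-3
China,low,60,L-3
Korea,low,59,L-3
Norway,low,59,L-3
United Arab Emirates,low,58,L-3
Bulgaria,low,57,L-3
Austria,low,57,L-3
Sweden,low,56,L-3
Croatia,low,56,L-3
Iceland,low,55,L-3
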